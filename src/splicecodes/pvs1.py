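"""Gene-configurable PVS1 decision tree and RNA-assay re-weighting.

The tree follows the loss-of-function assessment logic for splice-site
variants (out-of-frame with predicted nonsense-mediated decay at full
weight; in-frame and NMD-escaping outcomes weighted by criticality of the
removed region and the fraction of protein lost), with the splicing-
specific refinements: UTR-confined outcomes are not scored unless a
critical element is hit; in-frame removal of a region containing a
Pathogenic missense variant (or with Pathogenic variation at the
complementary splice site of the same exon) upweights to full PVS1; a
naturally occurring in-frame rescue transcript expressed at or above an
operational 10% of gene expression voids the code.

RNA assay read-outs re-enter the same tree: an observed aberration is
scored per transcript and pooled conservatively across complex read-outs;
an assay showing no aberration signals BP7_Strong(RNA) eligibility
instead.  Construct-only evidence (minigene/MPRA without matched-tissue
controls) and incomplete ("leaky") aberration each demote the result one
strength level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional, Sequence, Tuple, Union

from .transcript import RegionClass, Side

__all__ = [
    "EventType", "Frame", "AssaySource", "PVS1Strength",
    "SpliceEventPrediction", "CriticalDomain", "RescueTranscript",
    "GeneContext", "AssayThresholds", "AssayTranscript", "AssayReadout",
    "PVS1Result", "Bp7StrongRna", "LofMechanismNotEstablishedError",
    "assign_pvs1", "apply_rna_evidence", "pool_complex_readout", "demote",
]


class EventType(str, Enum):
    EXON_SKIP = "exon_skip"
    CRYPTIC_DONOR = "cryptic_donor"
    CRYPTIC_ACCEPTOR = "cryptic_acceptor"
    INTRON_RETENTION = "intron_retention"
    MULTI_EXON_SKIP = "multi_exon_skip"
    NO_IMPACT = "no_impact"


class Frame(str, Enum):
    IN_FRAME = "in_frame"
    OUT_OF_FRAME = "out_of_frame"


class AssaySource(str, Enum):
    PATIENT_RNA = "patient_rna"
    MINIGENE = "minigene"
    MPRA = "mpra"
    OTHER = "other"


class PVS1Strength(Enum):
    PVS1 = "PVS1"
    PVS1_STRONG = "PVS1_Strong"
    PVS1_MODERATE = "PVS1_Moderate"
    PVS1_SUPPORTING = "PVS1_Supporting"
    PVS1_NA = "PVS1_N/A"


_ORDER = [PVS1Strength.PVS1_NA, PVS1Strength.PVS1_SUPPORTING,
          PVS1Strength.PVS1_MODERATE, PVS1Strength.PVS1_STRONG,
          PVS1Strength.PVS1]


def strength_rank(s: PVS1Strength) -> int:
    return _ORDER.index(s)


def demote(s: PVS1Strength, levels: int = 1) -> PVS1Strength:
    return _ORDER[max(strength_rank(s) - levels, 0)]


def promote(s: PVS1Strength, levels: int = 1) -> PVS1Strength:
    return _ORDER[min(strength_rank(s) + levels, len(_ORDER) - 1)]


class LofMechanismNotEstablishedError(ValueError):
    """PVS1 is not applicable; consider PM4 for gain-of-function outcomes."""


@dataclass(frozen=True)
class SpliceEventPrediction:
    """Predicted (or observed) transcript-level consequence of a variant."""

    event_type: EventType
    affected_exons: Tuple[int, ...] = ()
    frame: Frame = Frame.IN_FRAME
    nmd_predicted: bool = False
    fraction_protein_removed: float = 0.0
    removes_critical_region: bool = False
    position_of_cryptic_site: Optional[int] = None
    utr_only: bool = False
    is_start_loss: bool = False
    removed_region: Optional[Tuple[int, int]] = None  # coding coordinates

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_protein_removed <= 1.0):
            raise ValueError("fraction_protein_removed must lie in [0, 1]")
        if self.nmd_predicted and self.frame is Frame.IN_FRAME:
            raise ValueError("NMD requires an out-of-frame outcome with a PTC")


@dataclass(frozen=True)
class CriticalDomain:
    start: int
    end: int
    evidence_tier: str = "functional"
    pathogenic_missense: bool = False


@dataclass(frozen=True)
class RescueTranscript:
    transcript_id: str
    skips_exons: Tuple[int, ...]
    expression_fraction: float
    encodes_functional_protein: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.expression_fraction <= 1.0):
            raise ValueError("expression_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class GeneContext:
    """Gene-specific knowledge feeding the decision tree."""

    gene: str = ""
    lof_mechanism_established: bool = True
    critical_domains: Tuple[CriticalDomain, ...] = ()
    rescue_transcripts: Tuple[RescueTranscript, ...] = ()
    protein_size_threshold: float = 0.10
    rescue_expression_threshold: float = 0.10
    start_loss_upweight: bool = False
    utr_critical_element: bool = False
    complementary_site_pathogenic: frozenset = frozenset()

    def __post_init__(self) -> None:
        for name in ("protein_size_threshold", "rescue_expression_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass(frozen=True)
class AssayThresholds:
    """Operational thresholds for interpreting splicing assay read-outs.

    ``complete_fraction`` is the aberrant fraction of variant-allele
    expression at or above which the read-out counts as complete/near-
    complete abrogation; it should be refined per gene and disease.
    """

    complete_fraction: float = 0.90

    def __post_init__(self) -> None:
        if not (0.0 < self.complete_fraction <= 1.0):
            raise ValueError("complete_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class AssayTranscript:
    prediction: SpliceEventPrediction
    aberrant_fraction: float
    allele_specific: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.aberrant_fraction <= 1.0):
            raise ValueError("aberrant_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class AssayReadout:
    transcripts: Tuple[AssayTranscript, ...]
    source: AssaySource = AssaySource.PATIENT_RNA
    controls_matched_tissue: bool = True
    psi: Optional[float] = None

    def __post_init__(self) -> None:
        total = sum(t.aberrant_fraction for t in self.transcripts)
        if total > 1.0 + 1e-6:
            raise ValueError("aberrant fractions must sum to <= 1 (remainder is full-length)")
        if self.psi is not None and not (0.0 <= self.psi <= 1.0):
            raise ValueError("psi must lie in [0, 1]")


@dataclass(frozen=True)
class PVS1Result:
    strength: PVS1Strength
    rna_based: bool = False
    rationale: Tuple[str, ...] = ()
    flags: frozenset = frozenset()
    per_transcript: Optional[Tuple[Tuple[str, PVS1Strength], ...]] = None


@dataclass(frozen=True)
class Bp7StrongRna:
    """Signal that assay data showed no splicing aberration, so
    BP7_Strong(RNA) is eligible in place of any PVS1-side code."""

    source: AssaySource
    rationale: Tuple[str, ...] = ()
    flags: frozenset = frozenset()


# decision-node labels; every leaf below is exercised by the test suite
NODE_LOF = "lof_mechanism_established"
LEAF_NO_IMPACT = "no_predicted_impact->PVS1_N/A"
LEAF_UTR_NA = "utr_only_no_critical_element->PVS1_N/A"
NODE_UTR_CRITICAL = "utr_only_but_critical_element"
LEAF_RESCUE = "plausible_rescue_transcript->PVS1_N/A"
LEAF_START_LOSS = "start_loss->PVS1_Moderate"
LEAF_START_LOSS_UP = "start_loss_upweighted->PVS1_Strong"
LEAF_OOF_NMD = "out_of_frame_nmd->PVS1"
LEAF_OOF_CRITICAL_UP = "out_of_frame_no_nmd_critical_upweighted->PVS1"
LEAF_OOF_CRITICAL = "out_of_frame_no_nmd_critical->PVS1_Strong"
LEAF_OOF_LARGE = "out_of_frame_no_nmd_gt_threshold->PVS1_Strong"
LEAF_OOF_SMALL = "out_of_frame_no_nmd_le_threshold->PVS1_Moderate"
LEAF_IF_CRITICAL_UP = "in_frame_critical_upweighted->PVS1"
LEAF_IF_CRITICAL = "in_frame_critical->PVS1_Strong"
LEAF_IF_LARGE = "in_frame_gt_threshold->PVS1_Strong"
LEAF_IF_SMALL = "in_frame_le_threshold->PVS1_Moderate"

ALL_LEAVES = frozenset({
    LEAF_NO_IMPACT, LEAF_UTR_NA, LEAF_RESCUE, LEAF_START_LOSS,
    LEAF_START_LOSS_UP, LEAF_OOF_NMD, LEAF_OOF_CRITICAL_UP, LEAF_OOF_CRITICAL,
    LEAF_OOF_LARGE, LEAF_OOF_SMALL, LEAF_IF_CRITICAL_UP, LEAF_IF_CRITICAL,
    LEAF_IF_LARGE, LEAF_IF_SMALL,
})


def _critical_assessment(pred: SpliceEventPrediction,
                         ctx: GeneContext) -> Tuple[bool, bool]:
    """(removes a critical region, that region carries a Pathogenic missense)."""
    overlapping = []
    if pred.removed_region is not None:
        lo, hi = pred.removed_region
        overlapping = [d for d in ctx.critical_domains
                       if d.start <= hi and lo <= d.end]
    is_critical = pred.removes_critical_region or bool(overlapping)
    if overlapping:
        missense = any(d.pathogenic_missense for d in overlapping)
    else:
        # no coordinates: the context's domain flags are taken to describe
        # the removed region asserted by the caller
        missense = (pred.removes_critical_region
                    and any(d.pathogenic_missense for d in ctx.critical_domains))
    return is_critical, missense


def _complementary_pathogenic(pred: SpliceEventPrediction, ctx: GeneContext) -> bool:
    return any(e in ctx.complementary_site_pathogenic for e in pred.affected_exons)


def _qualifying_rescue(pred: SpliceEventPrediction, ctx: GeneContext
                       ) -> Optional[RescueTranscript]:
    if not pred.affected_exons:
        return None
    for rt in ctx.rescue_transcripts:
        if (set(pred.affected_exons) <= set(rt.skips_exons)
                and rt.encodes_functional_protein
                and rt.expression_fraction >= ctx.rescue_expression_threshold):
            return rt
    return None


def assign_pvs1(pred: SpliceEventPrediction, ctx: GeneContext,
                region: Optional[RegionClass] = None) -> PVS1Result:
    """Run a predicted splicing outcome through the PVS1 decision tree.

    Raises :class:`LofMechanismNotEstablishedError` when loss of function
    is not an established disease mechanism for the gene (PM4 should be
    considered instead of PVS1 in that case).
    """
    if not ctx.lof_mechanism_established:
        raise LofMechanismNotEstablishedError(
            f"loss of function is not an established mechanism for "
            f"{ctx.gene or 'this gene'}; PVS1 is not applicable - consider PM4 "
            f"for predicted gain-of-function/length-change outcomes")
    if region is not None and region.side is Side.NONE and pred.event_type is EventType.NO_IMPACT:
        return PVS1Result(PVS1Strength.PVS1_NA, rationale=())

    trail: List[str] = [NODE_LOF]
    if pred.event_type is EventType.NO_IMPACT:
        trail.append(LEAF_NO_IMPACT)
        return PVS1Result(PVS1Strength.PVS1_NA, rationale=tuple(trail))
    if pred.utr_only:
        if not ctx.utr_critical_element:
            trail.append(LEAF_UTR_NA)
            return PVS1Result(PVS1Strength.PVS1_NA, rationale=tuple(trail))
        trail.append(NODE_UTR_CRITICAL)
    rescue = _qualifying_rescue(pred, ctx)
    if rescue is not None:
        trail.append(LEAF_RESCUE)
        return PVS1Result(PVS1Strength.PVS1_NA, rationale=tuple(trail),
                          flags=frozenset({f"rescue:{rescue.transcript_id}"}))
    if pred.is_start_loss:
        if ctx.start_loss_upweight:
            trail.append(LEAF_START_LOSS_UP)
            return PVS1Result(PVS1Strength.PVS1_STRONG, rationale=tuple(trail))
        trail.append(LEAF_START_LOSS)
        return PVS1Result(PVS1Strength.PVS1_MODERATE, rationale=tuple(trail))

    is_critical, missense = _critical_assessment(pred, ctx)
    upweight = missense or _complementary_pathogenic(pred, ctx)
    if pred.frame is Frame.OUT_OF_FRAME:
        if pred.nmd_predicted:
            trail.append(LEAF_OOF_NMD)
            return PVS1Result(PVS1Strength.PVS1, rationale=tuple(trail))
        if is_critical:
            if upweight:
                trail.append(LEAF_OOF_CRITICAL_UP)
                return PVS1Result(PVS1Strength.PVS1, rationale=tuple(trail))
            trail.append(LEAF_OOF_CRITICAL)
            return PVS1Result(PVS1Strength.PVS1_STRONG, rationale=tuple(trail))
        if pred.fraction_protein_removed > ctx.protein_size_threshold:
            trail.append(LEAF_OOF_LARGE)
            return PVS1Result(PVS1Strength.PVS1_STRONG, rationale=tuple(trail))
        trail.append(LEAF_OOF_SMALL)
        return PVS1Result(PVS1Strength.PVS1_MODERATE, rationale=tuple(trail))

    # in-frame outcome
    if is_critical:
        if upweight:
            trail.append(LEAF_IF_CRITICAL_UP)
            return PVS1Result(PVS1Strength.PVS1, rationale=tuple(trail))
        trail.append(LEAF_IF_CRITICAL)
        return PVS1Result(PVS1Strength.PVS1_STRONG, rationale=tuple(trail))
    if pred.fraction_protein_removed > ctx.protein_size_threshold:
        trail.append(LEAF_IF_LARGE)
        return PVS1Result(PVS1Strength.PVS1_STRONG, rationale=tuple(trail))
    trail.append(LEAF_IF_SMALL)
    return PVS1Result(PVS1Strength.PVS1_MODERATE, rationale=tuple(trail))


def pool_complex_readout(per_transcript: Sequence[Tuple[PVS1Result, float]],
                         thresholds: AssayThresholds = AssayThresholds(),
                         ) -> PVS1Result:
    """Pool per-transcript strengths of a complex read-out conservatively.

    Transcripts are grouped by strength; walking from the strongest group
    down, the overall strength is the group at which the cumulative
    aberrant contribution first reaches the complete/near-complete
    threshold.  If the aberrant transcripts never reach it (i.e. the
    full-length transcript exceeds 1 - threshold), the read-out is leaky:
    the strongest aberrant strength is demoted one level and flagged.
    """
    if not per_transcript:
        raise ValueError("per_transcript must be non-empty")
    total = sum(c for _, c in per_transcript)
    if total > 1.0 + 1e-6:
        raise ValueError("contributions must sum to <= 1 (remainder is full-length)")
    ordered = sorted(per_transcript, key=lambda rc: -strength_rank(rc[0].strength))
    per_tx = tuple((" > ".join(r.rationale) or r.strength.value, r.strength)
                   for r, _ in ordered)
    cum = 0.0
    overall: Optional[PVS1Strength] = None
    for res, contrib in ordered:
        cum += contrib
        if cum >= thresholds.complete_fraction - 1e-9:
            overall = res.strength
            break
    if overall is not None:
        return PVS1Result(overall, rna_based=True, per_transcript=per_tx,
                          rationale=("pooled_complex_readout",))
    strongest = ordered[0][0].strength
    return PVS1Result(demote(strongest), rna_based=True, per_transcript=per_tx,
                      rationale=("pooled_complex_readout", "leaky_below_threshold"),
                      flags=frozenset({"LEAKY"}))


def apply_rna_evidence(baseline: Optional[PVS1Result], readout: AssayReadout,
                       ctx: GeneContext,
                       thresholds: AssayThresholds = AssayThresholds(),
                       ) -> Union[PVS1Result, Bp7StrongRna]:
    """Re-weight PVS1 from an RNA assay read-out, or signal BP7_Strong(RNA).

    A read-out with no aberrant transcripts returns a
    :class:`Bp7StrongRna` signal.  Otherwise each observed aberration is
    scored through the decision tree and pooled; read-outs below the
    complete/near-complete threshold demote one level (LEAKY), and
    construct-only evidence (non-patient RNA, or controls not from
    matched tissue) demotes one further level (CONSTRUCT_ONLY).
    """
    construct_only = (readout.source is not AssaySource.PATIENT_RNA
                      or not readout.controls_matched_tissue)
    flags = set()
    if construct_only:
        flags.add("CONSTRUCT_ONLY")
    aberrant = [t for t in readout.transcripts
                if t.prediction.event_type is not EventType.NO_IMPACT
                and t.aberrant_fraction > 0.0]
    if not aberrant:
        return Bp7StrongRna(source=readout.source,
                            rationale=("no_aberrant_transcripts_vs_controls",),
                            flags=frozenset(flags))
    scored = [(assign_pvs1(t.prediction, ctx), t.aberrant_fraction) for t in aberrant]
    pooled = pool_complex_readout(scored, thresholds=thresholds)
    strength = pooled.strength
    flags |= set(pooled.flags)
    rationale = tuple(pooled.rationale)
    if construct_only and strength is not PVS1Strength.PVS1_NA:
        strength = demote(strength)
        rationale = rationale + ("construct_only_downweight",)
    return PVS1Result(strength, rna_based=True, rationale=rationale,
                      flags=frozenset(flags), per_transcript=pooled.per_transcript)
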