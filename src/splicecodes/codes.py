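"""Assignment and combination of splicing-related ACMG/AMP evidence codes.

PP3/BP4 are assigned from the calibrated prediction-score cut-offs (the
high cut reaches a moderate level of evidence, but the codes are applied
at supporting weight by default, the conservative recommendation); BP7 is
a position code dependent on BP4; PS1 transfers evidence from a
previously classified variant with the exact same predicted splicing
event; and :func:`combine_codes` applies the combination rules: canonical
dinucleotide variants follow the PVS1 path only, assay-derived
PVS1(RNA) replaces the prediction codes, assay-confirmed absence of
aberration yields BP7_Strong(RNA) (recorded but not applied for coding
variants lacking protein-level functional data), and PS3/BS3 are never
assigned for splicing-only evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional, Sequence, Tuple, Union

from .pvs1 import (AssaySource, Bp7StrongRna, EventType, PVS1Result,
                   PVS1Strength, SpliceEventPrediction)
from .transcript import (RegionCategory, RegionClass, RegionConfig, Side,
                         bp7_position_eligible)

__all__ = [
    "SpliceAIScores", "Classification", "ComparatorVariant", "Consequence",
    "Code", "CodeSet", "CodeStrength", "ConflictingEvidenceError",
    "assign_pp3_bp4", "assign_bp7", "assign_ps1", "combine_codes",
]


class CodeStrength(str, Enum):
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"


class Classification(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"


class Consequence(str, Enum):
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    MISSENSE = "missense"
    INFRAME_INDEL = "inframe_indel"
    OTHER = "other"


class ConflictingEvidenceError(ValueError):
    """RNA evidence simultaneously claims aberration and no impact."""


@dataclass(frozen=True)
class SpliceAIScores:
    """The four delta scores (acceptor/donor gain and loss), plus the
    optional positions of the predicted events relative to the variant."""

    ds_ag: float
    ds_al: float
    ds_dg: float
    ds_dl: float
    dp_ag: Optional[int] = None
    dp_al: Optional[int] = None
    dp_dg: Optional[int] = None
    dp_dl: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("ds_ag", "ds_al", "ds_dg", "ds_dl"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def max_delta(self) -> float:
        """Maximum probability of altered splicing across the four outputs."""
        return max(self.ds_ag, self.ds_al, self.ds_dg, self.ds_dl)


@dataclass(frozen=True)
class ComparatorVariant:
    """A previously classified (Likely) Pathogenic variant used for PS1."""

    variant_key: str
    classification: Classification
    region: RegionClass
    predicted_event: SpliceEventPrediction
    prediction_strength: float
    same_nucleotide_as_vua: bool = False
    same_motif_as_vua: bool = False
    clinical_support_flag: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.prediction_strength <= 1.0):
            raise ValueError("prediction_strength must lie in [0, 1]")


@dataclass(frozen=True)
class Code:
    name: str
    strength: CodeStrength
    rna: bool = False
    rationale: str = ""


@dataclass
class CodeSet:
    """Final code assignments with mutual-exclusion bookkeeping."""

    assigned: List[Code] = field(default_factory=list)
    suppressed: List[Tuple[str, str]] = field(default_factory=list)
    record_only: List[str] = field(default_factory=list)

    def names(self) -> List[str]:
        return [c.name for c in self.assigned]

    def get(self, name: str) -> Optional[Code]:
        for c in self.assigned:
            if c.name == name:
                return c
        return None

    def validate(self) -> None:
        names = self.names()
        if "PP3" in names and any(n.startswith("PVS1") for n in names):
            raise ValueError("PP3 must not be co-assigned with any PVS1 code")
        if "PP3" in names and "BP4" in names:
            raise ValueError("PP3 and BP4 are mutually exclusive")
        if "PS3" in names or "BS3" in names:
            raise ValueError("PS3/BS3 must not be assigned for splicing-only evidence")
        bp7 = self.get("BP7")
        if bp7 is not None and not bp7.rna and "BP4" not in names:
            raise ValueError("computational BP7 requires BP4")


def assign_pp3_bp4(scores: Optional[SpliceAIScores], low_cut: float = 0.1,
                   high_cut: float = 0.2,
                   applied_weight: CodeStrength = CodeStrength.SUPPORTING,
                   ) -> Optional[Code]:
    """PP3/BP4 from the maximum delta score at calibrated cut-offs.

    Intended for variants outside the canonical dinucleotides (canonical
    positions follow the PVS1 path).  Scores in the uninformative band
    yield no code; missing scores yield no code.
    """
    if scores is None:
        return None
    if applied_weight not in (CodeStrength.SUPPORTING, CodeStrength.MODERATE):
        raise ValueError("applied_weight must be supporting or moderate")
    m = scores.max_delta
    if m >= high_cut:
        return Code("PP3", applied_weight,
                    rationale=f"max delta {m:g} >= {high_cut:g}")
    if m <= low_cut:
        return Code("BP4", applied_weight,
                    rationale=f"max delta {m:g} <= {low_cut:g}")
    return None


def assign_bp7(bp4_met: bool, position_eligible: bool) -> Optional[Code]:
    """Computational BP7: position-eligible and dependent on BP4.

    Evolutionary conservation is deliberately not an input.
    """
    if bp4_met and position_eligible:
        return Code("BP7", CodeStrength.SUPPORTING,
                    rationale="BP4 met; position outside designated splice region")
    return None


def _events_match(a: SpliceEventPrediction, b: SpliceEventPrediction) -> bool:
    return (a.event_type is b.event_type
            and tuple(a.affected_exons) == tuple(b.affected_exons)
            and a.position_of_cryptic_site == b.position_of_cryptic_site)


def assign_ps1(vua_region: RegionClass, vua_pvs1: Optional[PVS1Result],
               vua_event: SpliceEventPrediction, vua_strength: float,
               comparator: ComparatorVariant,
               tolerance: float = 0.05) -> Optional[Code]:
    """PS1 by similarity of predicted splicing events.

    Prerequisites: the comparator's predicted event must precisely match
    the variant under assessment's (same event type, exons, cryptic
    position) and the VUA's prediction strength must be within
    ``tolerance`` of (or above) the comparator's.  The weight matrix then
    depends on whether the VUA sits at a canonical dinucleotide, its
    baseline PVS1 weight, the comparator's position relative to the VUA,
    and the comparator's classification; Likely Pathogenic comparators
    located at canonical positions additionally require independent
    clinical support.
    """
    if not _events_match(vua_event, comparator.predicted_event):
        return None
    if vua_strength < comparator.prediction_strength - tolerance:
        return None
    same_nt = comparator.same_nucleotide_as_vua
    same_motif = comparator.same_motif_as_vua or same_nt
    if not same_motif:
        return None
    is_lp = comparator.classification is Classification.LIKELY_PATHOGENIC
    comp_canonical = comparator.region.category is RegionCategory.CANONICAL_DINUCLEOTIDE

    vua_canonical = vua_region.category is RegionCategory.CANONICAL_DINUCLEOTIDE
    if not vua_canonical:
        # Likely Pathogenic canonical-position comparators carry their own
        # positional prior; they require independent clinical support
        if is_lp and comp_canonical and not comparator.clinical_support_flag:
            return None
        if same_nt:
            return Code("PS1",
                        CodeStrength.MODERATE if is_lp else CodeStrength.STRONG,
                        rationale="same nucleotide, same predicted event")
        return Code("PS1",
                    CodeStrength.SUPPORTING if is_lp else CodeStrength.MODERATE,
                    rationale="same splice motif, same predicted event")

    # VUA at a canonical dinucleotide: weights depend on its baseline PVS1
    baseline = vua_pvs1.strength if vua_pvs1 is not None else None
    if baseline is None or baseline is PVS1Strength.PVS1_NA:
        return None
    full = baseline is PVS1Strength.PVS1
    if comp_canonical:
        if is_lp:
            return None  # would overweight relative to the comparator
        return Code("PS1",
                    CodeStrength.SUPPORTING if full else CodeStrength.STRONG,
                    rationale="canonical VUA, Pathogenic comparator in same dinucleotide")
    if full:
        return Code("PS1", CodeStrength.SUPPORTING,
                    rationale="canonical VUA at full PVS1, comparator in same motif")
    return Code("PS1",
                CodeStrength.SUPPORTING if is_lp else CodeStrength.MODERATE,
                rationale="canonical VUA below full PVS1, comparator in same motif")


_PVS1_CODE_STRENGTH = {
    PVS1Strength.PVS1: CodeStrength.VERY_STRONG,
    PVS1Strength.PVS1_STRONG: CodeStrength.STRONG,
    PVS1Strength.PVS1_MODERATE: CodeStrength.MODERATE,
    PVS1Strength.PVS1_SUPPORTING: CodeStrength.SUPPORTING,
}


def _pvs1_code(result: PVS1Result) -> Optional[Code]:
    if result.strength is PVS1Strength.PVS1_NA:
        return None
    return Code("PVS1", _PVS1_CODE_STRENGTH[result.strength], rna=result.rna_based,
                rationale=" > ".join(result.rationale))


def combine_codes(region: RegionClass, consequence: Consequence,
                  scores: Optional[SpliceAIScores] = None,
                  pvs1: Optional[PVS1Result] = None,
                  rna_result: Optional[Union[PVS1Result, Bp7StrongRna]] = None,
                  ps1: Optional[Code] = None,
                  protein_functional_no_impact: Optional[bool] = None,
                  low_cut: float = 0.1, high_cut: float = 0.2,
                  applied_weight: CodeStrength = CodeStrength.SUPPORTING,
                  region_mode: str = "standard",
                  cfg: RegionConfig = RegionConfig()) -> CodeSet:
    """Combine position, prediction, comparator and assay evidence into a
    final code set for one variant/transcript pair.

    The same cut-offs drive both this function and the calibration module;
    change them in one configuration and both move together.
    """
    rna_aberration = isinstance(rna_result, PVS1Result)
    rna_no_impact = isinstance(rna_result, Bp7StrongRna)
    if rna_aberration and rna_no_impact:  # pragma: no cover - types exclude this
        raise ConflictingEvidenceError("aberration and no-impact cannot co-occur")
    if rna_aberration and not rna_result.rna_based:
        raise ValueError("rna_result must carry rna_based=True")
    if pvs1 is not None and pvs1.rna_based and rna_no_impact:
        raise ConflictingEvidenceError(
            "RNA-derived PVS1 contradicts an RNA no-impact signal")

    out = CodeSet()
    out.suppressed.append(("PS3", "splicing assay evidence is captured as "
                           "PVS1_Strength(RNA), not PS3"))
    out.suppressed.append(("BS3", "absence of splicing impact is captured as "
                           "BP7_Strong(RNA), not BS3"))

    canonical = region.category is RegionCategory.CANONICAL_DINUCLEOTIDE
    coding_non_splice = consequence in (Consequence.MISSENSE, Consequence.INFRAME_INDEL)

    if canonical:
        base = rna_result if rna_aberration else pvs1
        if rna_aberration and pvs1 is not None and not pvs1.rna_based:
            out.record_only.append(
                f"predictive PVS1 ({pvs1.strength.value}) superseded by assay data")
        if isinstance(base, PVS1Result):
            code = _pvs1_code(base)
            if code is not None:
                out.assigned.append(code)
            else:
                out.record_only.append("PVS1_N/A: " + (" > ".join(base.rationale)
                                                       or "no scorable outcome"))
        if rna_no_impact:
            out.assigned.append(Code("BP7", CodeStrength.STRONG, rna=True,
                                     rationale="assay shows no splicing aberration"))
            if pvs1 is not None:
                out.record_only.append(
                    f"predictive PVS1 ({pvs1.strength.value}) contradicted by assay")
        if scores is not None:
            out.suppressed.append(("PP3", "canonical dinucleotide variants follow "
                                   "the PVS1 path; PP3 not applied"))
            out.suppressed.append(("BP4", "canonical dinucleotide variants follow "
                                   "the PVS1 path; BP4 not applied"))
    elif rna_aberration:
        code = _pvs1_code(rna_result)
        if code is not None:
            out.assigned.append(code)
        else:
            out.record_only.append("assay aberration scored PVS1_N/A: "
                                   + " > ".join(rna_result.rationale))
        out.suppressed.append(("PP3", "replaced by experimentally derived PVS1(RNA)"))
        out.suppressed.append(("BP4", "replaced by experimentally derived PVS1(RNA)"))
    elif rna_no_impact and not coding_non_splice:
        out.assigned.append(Code("BP7", CodeStrength.STRONG, rna=True,
                                 rationale="assay shows no splicing aberration"))
        out.suppressed.append(("BP4", "superseded by BP7_Strong(RNA)"))
        out.suppressed.append(("BP7", "computational BP7 superseded by BP7_Strong(RNA)"))
    elif rna_no_impact and coding_non_splice and protein_functional_no_impact:
        out.assigned.append(Code("BP7", CodeStrength.STRONG, rna=True,
                                 rationale="no splicing aberration and protein-level "
                                           "functional impact excluded"))
        out.suppressed.append(("BP4", "superseded by BP7_Strong(RNA)"))
    else:
        if rna_no_impact:  # coding variant without protein functional data
            out.record_only.append(
                "splicing assay shows no aberration; BP7_Strong(RNA) withheld "
                "pending protein-level functional data - most deleterious "
                "predicted effect retained")
        pred_code = assign_pp3_bp4(scores, low_cut=low_cut, high_cut=high_cut,
                                   applied_weight=applied_weight)
        if pred_code is None and scores is None:
            out.record_only.append("no prediction scores available; PP3/BP4 not assessed")
        if pred_code is not None:
            if pred_code.name == "PP3" and coding_non_splice:
                pred_code = Code("PP3", pred_code.strength,
                                 rationale=pred_code.rationale
                                 + "; splicing component only - protein-level "
                                   "impact assessed separately")
            out.assigned.append(pred_code)
        bp4_met = pred_code is not None and pred_code.name == "BP4"
        eligible = bp7_position_eligible(
            region, is_synonymous=consequence is Consequence.SYNONYMOUS,
            cfg=cfg, region_mode=region_mode)
        bp7 = assign_bp7(bp4_met, eligible)
        if bp7 is not None and not rna_no_impact:
            out.assigned.append(bp7)

    if ps1 is not None:
        out.assigned.append(ps1)

    out.validate()
    return out
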