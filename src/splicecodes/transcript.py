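"""Transcript models and splice-region classification.

Coordinates are 1-based, fully closed genomic intervals (GTF convention).
Offsets are reported in transcript orientation, HGVS intron-numbering style:

* donor side:    last exonic base is -1, first intronic base is +1;
* acceptor side: first exonic base is +1, last intronic base (adjacent to
  the exon) is -1, so deeper intronic positions are -2, -3, ...

The region vocabulary follows the standard splice-motif designations used
for U2-type GT-AG introns: the *canonical dinucleotide* is the intronic
+/-1,2 positions; the *standard splice region* spans the last 3 exonic and
first 6 intronic bases at the donor, and the first exonic base plus 20
intronic bases at the acceptor; the *minimal splice region* keeps the same
donor window but restricts the acceptor to 3 intronic bases.  All windows
are configurable (e.g. a 9-nt donor for U12-type introns).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Tuple


class Side(str, Enum):
    DONOR = "donor"
    ACCEPTOR = "acceptor"
    NONE = "none"


class RegionCategory(str, Enum):
    CANONICAL_DINUCLEOTIDE = "canonical"
    MINIMAL_SPLICE_REGION = "minimal"
    STANDARD_SPLICE_REGION = "standard"
    OUTSIDE = "outside"


#: ordering from most to least motif-proximal, used for multi-base variants
CATEGORY_RANK = {
    RegionCategory.CANONICAL_DINUCLEOTIDE: 0,
    RegionCategory.MINIMAL_SPLICE_REGION: 1,
    RegionCategory.STANDARD_SPLICE_REGION: 2,
    RegionCategory.OUTSIDE: 3,
}


class PositionOutsideTranscriptError(ValueError):
    """Raised when a variant does not overlap the transcript span."""


@dataclass(frozen=True)
class VariantAllele:
    """A single variant allele in VCF-like representation (1-based pos)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")


@dataclass(frozen=True)
class RegionConfig:
    """Splice-motif window sizes, in bases, counted from the exon boundary.

    Defaults describe U2-type GT-AG introns.  ``bp7_intronic_bound_donor``
    and the acceptor bounds give the first intronic offset at which the
    position-based BP7 code becomes applicable (+7 / -21 standard, -4
    minimal).
    """

    donor_exonic: int = 3
    donor_intronic: int = 6
    acceptor_exonic: int = 1
    acceptor_intronic_standard: int = 20
    acceptor_intronic_minimal: int = 3
    bp7_intronic_bound_donor: int = 7
    bp7_intronic_bound_acceptor: int = -21
    bp7_intronic_bound_acceptor_minimal: int = -4

    def __post_init__(self) -> None:
        for name in ("donor_exonic", "donor_intronic", "acceptor_exonic",
                     "acceptor_intronic_standard", "acceptor_intronic_minimal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.acceptor_intronic_minimal > self.acceptor_intronic_standard:
            raise ValueError("minimal acceptor window cannot exceed the standard window")


@dataclass(frozen=True)
class RegionClass:
    """Position category of a variant relative to the nearest splice motifs."""

    category: RegionCategory
    side: Side
    offset: int
    exonic: bool = False

    def __post_init__(self) -> None:
        if self.category is RegionCategory.CANONICAL_DINUCLEOTIDE:
            if self.exonic or abs(self.offset) not in (1, 2):
                raise ValueError("canonical dinucleotide implies intronic offset +/-1 or +/-2")


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered list of exons, in transcription order.

    ``exons`` holds (start, end) genomic intervals, start <= end, ordered in
    the direction of transcription (descending genomic coordinates on the
    minus strand).
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript must have at least one exon")
        for s, e in self.exons:
            if e < s:
                raise ValueError(f"exon interval ({s}, {e}) has end < start")
        starts = [s for s, _ in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise ValueError("exons must be given in transcription order")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise ValueError("exons overlap or abut without an intron")

    @classmethod
    def from_genomic_exons(cls, transcript_id: str, chrom: str, strand: str,
                           exons: Sequence[Tuple[int, int]], **kw) -> "TranscriptModel":
        """Build from exons in any order; sorts them into transcription order."""
        ordered = sorted(exons, reverse=(strand == "-"))
        return cls(transcript_id, chrom, strand, tuple(tuple(e) for e in ordered), **kw)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> Tuple[int, int]:
        lo = min(s for s, _ in self.exons)
        hi = max(e for _, e in self.exons)
        return lo, hi

    def _direction(self) -> int:
        return 1 if self.strand == "+" else -1

    def donor_boundary(self, exon_index: int) -> int:
        """Genomic coordinate of the last exonic base on the donor side."""
        s, e = self.exons[exon_index]
        return e if self.strand == "+" else s

    def acceptor_boundary(self, exon_index: int) -> int:
        """Genomic coordinate of the first exonic base on the acceptor side."""
        s, e = self.exons[exon_index]
        return s if self.strand == "+" else e


def _locate(tx: TranscriptModel, pos: int) -> Tuple[str, int]:
    """Return ('exon', i) or ('intron', i) with i a transcription-order index.

    Intron i lies between transcription exons i and i+1.
    """
    lo, hi = tx.span
    if pos < lo or pos > hi:
        raise PositionOutsideTranscriptError(
            f"position {pos} outside span {lo}-{hi} of {tx.transcript_id}")
    for i, (s, e) in enumerate(tx.exons):
        if s <= pos <= e:
            return "exon", i
    for i in range(tx.n_exons - 1):
        a = tx.exons[i]
        b = tx.exons[i + 1]
        lo_i = min(a[1], b[1]) + 1
        hi_i = max(a[0], b[0]) - 1
        if lo_i <= pos <= hi_i:
            return "intron", i
    raise PositionOutsideTranscriptError(
        f"position {pos} not locatable within {tx.transcript_id}")


def _exon_offsets(tx: TranscriptModel, i: int, pos: int) -> Tuple[Optional[int], Optional[int]]:
    """(donor_offset, acceptor_offset) of an exonic base; None for absent sides."""
    d = tx._direction()
    donor_off = (pos - tx.donor_boundary(i)) * d - 1  # last exonic base -> -1
    acceptor_off = (pos - tx.acceptor_boundary(i)) * d + 1  # first exonic base -> +1
    if i == tx.n_exons - 1:
        donor_off = None
    if i == 0:
        acceptor_off = None
    return donor_off, acceptor_off


def _intron_offsets(tx: TranscriptModel, i: int, pos: int) -> Tuple[int, int]:
    """(donor_offset, acceptor_offset) of an intronic base in intron i."""
    d = tx._direction()
    donor_off = (pos - tx.donor_boundary(i)) * d          # first intronic base -> +1
    acceptor_off = (pos - tx.acceptor_boundary(i + 1)) * d  # last intronic base -> -1
    return donor_off, acceptor_off


def hgvs_like_offset(variant: VariantAllele, tx: TranscriptModel) -> Tuple[Side, int, bool]:
    """Signed distance of a variant position from its nearest exon boundary.

    Returns ``(side, offset, exonic_flag)`` with the offset in transcript
    orientation (see module docstring).  The nearest boundary wins; exact
    ties resolve to the donor side.  Positions in a terminal exon only see
    the boundary that exists there; a single-exon transcript reports
    ``(Side.NONE, 0, True)``.
    """
    where, i = _locate(tx, variant.pos)
    if where == "exon":
        donor_off, acceptor_off = _exon_offsets(tx, i, variant.pos)
        exonic = True
    else:
        donor_off, acceptor_off = _intron_offsets(tx, i, variant.pos)
        exonic = False
    if donor_off is None and acceptor_off is None:
        return Side.NONE, 0, exonic
    if acceptor_off is None:
        return Side.DONOR, donor_off, exonic
    if donor_off is None:
        return Side.ACCEPTOR, acceptor_off, exonic
    if abs(donor_off) <= abs(acceptor_off):
        return Side.DONOR, donor_off, exonic
    return Side.ACCEPTOR, acceptor_off, exonic


def _classify_base(pos: int, tx: TranscriptModel, cfg: RegionConfig) -> RegionClass:
    where, i = _locate(tx, pos)
    if where == "exon":
        donor_off, acceptor_off = _exon_offsets(tx, i, pos)
        in_donor = donor_off is not None and -cfg.donor_exonic <= donor_off <= -1
        in_acceptor = acceptor_off is not None and 1 <= acceptor_off <= cfg.acceptor_exonic
        # exonic windows are identical in the standard and minimal designations
        if in_donor and in_acceptor:
            side, off = ((Side.DONOR, donor_off)
                         if abs(donor_off) <= abs(acceptor_off)
                         else (Side.ACCEPTOR, acceptor_off))
            return RegionClass(RegionCategory.MINIMAL_SPLICE_REGION, side, off, exonic=True)
        if in_donor:
            return RegionClass(RegionCategory.MINIMAL_SPLICE_REGION, Side.DONOR, donor_off, exonic=True)
        if in_acceptor:
            return RegionClass(RegionCategory.MINIMAL_SPLICE_REGION, Side.ACCEPTOR, acceptor_off, exonic=True)
        side, off, _ = hgvs_like_offset(VariantAllele(tx.chrom, pos, "N", "A"), tx)
        return RegionClass(RegionCategory.OUTSIDE, side, off, exonic=True)

    donor_off, acceptor_off = _intron_offsets(tx, i, pos)
    canon_donor = donor_off in (1, 2)
    canon_acceptor = acceptor_off in (-1, -2)
    if canon_donor or canon_acceptor:
        if canon_donor and (not canon_acceptor or abs(donor_off) <= abs(acceptor_off)):
            return RegionClass(RegionCategory.CANONICAL_DINUCLEOTIDE, Side.DONOR, donor_off)
        return RegionClass(RegionCategory.CANONICAL_DINUCLEOTIDE, Side.ACCEPTOR, acceptor_off)
    min_donor = 1 <= donor_off <= cfg.donor_intronic
    min_acceptor = -cfg.acceptor_intronic_minimal <= acceptor_off <= -1
    if min_donor or min_acceptor:
        if min_donor and (not min_acceptor or abs(donor_off) <= abs(acceptor_off)):
            return RegionClass(RegionCategory.MINIMAL_SPLICE_REGION, Side.DONOR, donor_off)
        return RegionClass(RegionCategory.MINIMAL_SPLICE_REGION, Side.ACCEPTOR, acceptor_off)
    std_acceptor = -cfg.acceptor_intronic_standard <= acceptor_off <= -1
    if std_acceptor:
        return RegionClass(RegionCategory.STANDARD_SPLICE_REGION, Side.ACCEPTOR, acceptor_off)
    if abs(donor_off) <= abs(acceptor_off):
        return RegionClass(RegionCategory.OUTSIDE, Side.DONOR, donor_off)
    return RegionClass(RegionCategory.OUTSIDE, Side.ACCEPTOR, acceptor_off)


def classify_region(variant: VariantAllele, tx: TranscriptModel,
                    cfg: RegionConfig = RegionConfig()) -> RegionClass:
    """Classify a variant into a splice-region category.

    Multi-nucleotide variants are classified by the most motif-proximal
    base they affect (so a deletion spanning a canonical dinucleotide is
    CANONICAL).  Insertions affect the anchor base and the base after it.
    """
    span_len = max(len(variant.ref), 1)
    positions = list(range(variant.pos, variant.pos + span_len))
    if len(variant.alt) > len(variant.ref):
        positions.append(variant.pos + span_len)
    lo, hi = tx.span
    positions = [p for p in positions if lo <= p <= hi]
    if not positions:
        raise PositionOutsideTranscriptError(
            f"variant at {variant.pos} does not overlap {tx.transcript_id}")
    classes = [_classify_base(p, tx, cfg) for p in positions]
    return min(classes, key=lambda rc: (CATEGORY_RANK[rc.category], abs(rc.offset)))


def bp7_position_eligible(rc: RegionClass, is_synonymous: bool,
                          cfg: RegionConfig = RegionConfig(),
                          region_mode: str = "standard") -> bool:
    """Whether a variant position qualifies for the computational BP7 code.

    Intronic variants qualify at or beyond +7 (donor side) and -21
    (acceptor side; -4 in ``minimal`` mode).  Synonymous exonic variants
    qualify unless they sit in the last three bases or the first base of
    an exon.  Conservation is deliberately not an input.
    """
    if region_mode not in ("standard", "minimal"):
        raise ValueError(f"region_mode must be 'standard' or 'minimal', got {region_mode!r}")
    if rc.exonic:
        return is_synonymous and rc.category is RegionCategory.OUTSIDE
    if rc.side is Side.NONE:
        return False
    if region_mode == "standard":
        if rc.category is not RegionCategory.OUTSIDE:
            return False
        acceptor_bound = cfg.bp7_intronic_bound_acceptor
    else:
        if rc.category in (RegionCategory.CANONICAL_DINUCLEOTIDE,
                           RegionCategory.MINIMAL_SPLICE_REGION):
            return False
        acceptor_bound = cfg.bp7_intronic_bound_acceptor_minimal
    if rc.side is Side.DONOR:
        return rc.offset >= cfg.bp7_intronic_bound_donor
    return rc.offset <= acceptor_bound
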