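"""Synthetic truth datasets, transcript fixtures and assay read-outs.

These generators define the conditions under which the calibration and
rule engines are exercised and tested.  The default score distributions
are Beta laws fitted once to the marginal structure of the curated 8-gene
truth set (2246 non-spliceogenic / 491 spliceogenic variants outside
canonical sites, with 87% / 8% / 5% of negatives and 15% / 8% / 78% of
positives in the <=0.1, 0.1-0.2 and >=0.2 score zones): negatives
Beta(0.22, 5.40), positives Beta(0.58, 0.43).  The distributions are test
instruments, not a motif-position model of real SpliceAI output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .calibration import TruthRecord
from .transcript import RegionCategory, RegionClass, Side, TranscriptModel

__all__ = [
    "SimConfig", "generate_truth_dataset", "curated_truth_fixture",
    "resampled_truth_dataset", "generate_from_bin_probs",
    "make_fixture_transcript", "representative_region",
]

DistSpec = Union[Tuple[float, float], float]

#: counts of the three-score-zone calibration table for the curated truth
#: set: rows = (non-spliceogenic, spliceogenic), columns = (<=0.1, mid, >=0.2)
CURATED_TRUTH_COUNTS = ((1962, 175, 109), (72, 38, 381))
CURATED_TRUTH_N_NEG = sum(CURATED_TRUTH_COUNTS[0])
CURATED_TRUTH_N_POS = sum(CURATED_TRUTH_COUNTS[1])


def representative_region(category: RegionCategory) -> RegionClass:
    """A valid RegionClass instance for a bare category label."""
    if category is RegionCategory.CANONICAL_DINUCLEOTIDE:
        return RegionClass(category, Side.DONOR, 1)
    if category is RegionCategory.MINIMAL_SPLICE_REGION:
        return RegionClass(category, Side.ACCEPTOR, -3)
    if category is RegionCategory.STANDARD_SPLICE_REGION:
        return RegionClass(category, Side.ACCEPTOR, -15)
    return RegionClass(RegionCategory.OUTSIDE, Side.DONOR, 50)


@dataclass(frozen=True)
class SimConfig:
    """Configuration for a synthetic truth dataset.

    Score distributions are either ``(a, b)`` Beta shape pairs or a float
    for a point mass.
    """

    n_pos: int
    n_neg: int
    pos_score_dist: DistSpec = (0.58, 0.43)
    neg_score_dist: DistSpec = (0.22, 5.40)
    region_mix: Optional[Mapping[RegionCategory, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos <= 0 or self.n_neg <= 0:
            raise ValueError("class counts must be positive")
        for spec in (self.pos_score_dist, self.neg_score_dist):
            if isinstance(spec, tuple):
                a, b = spec
                if a <= 0 or b <= 0:
                    raise ValueError(f"Beta parameters must be positive, got {spec}")
            else:
                if not (0.0 <= float(spec) <= 1.0):
                    raise ValueError("point-mass score must lie in [0, 1]")
        if self.region_mix is not None:
            total = sum(self.region_mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"region_mix proportions must sum to 1, got {total}")


def _draw_scores(spec: DistSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec, tuple):
        return rng.beta(spec[0], spec[1], size=n)
    return np.full(n, float(spec))


def generate_truth_dataset(cfg: SimConfig) -> List[TruthRecord]:
    """Draw a seed-deterministic truth dataset from the configuration."""
    rng = np.random.default_rng(cfg.seed)
    mix = cfg.region_mix or {RegionCategory.OUTSIDE: 1.0}
    cats = list(mix.keys())
    probs = np.array([mix[c] for c in cats], dtype=float)
    records: List[TruthRecord] = []
    for label, n, spec, prefix in ((True, cfg.n_pos, cfg.pos_score_dist, "pos"),
                                   (False, cfg.n_neg, cfg.neg_score_dist, "neg")):
        scores = np.clip(_draw_scores(spec, n, rng), 0.0, 1.0)
        region_idx = rng.choice(len(cats), size=n, p=probs)
        for k in range(n):
            records.append(TruthRecord(
                variant_key=f"{prefix}_{k + 1:05d}",
                score=float(scores[k]),
                spliceogenic=label,
                region=representative_region(cats[region_idx[k]])))
    return records


def _zone_scores(counts: Sequence[int]) -> np.ndarray:
    """Deterministic scores matching the three printed zones.

    Scores are evenly spaced inside each zone; the closed outer edges
    (0.1 for the low zone, 0.2 for the high zone) are included, the open
    middle zone stays strictly inside (0.1, 0.2).
    """
    n_low, n_mid, n_high = counts
    low = np.linspace(0.0, 0.1, n_low) if n_low else np.empty(0)
    mid = np.linspace(0.101, 0.199, n_mid) if n_mid else np.empty(0)
    high = np.linspace(0.2, 1.0, n_high) if n_high else np.empty(0)
    return np.concatenate([low, mid, high])


def curated_truth_fixture() -> List[TruthRecord]:
    """The curated-truth-set calibration table as a deterministic dataset.

    Emits exactly 2246 non-spliceogenic and 491 spliceogenic records whose
    scores land in the three zones with the published counts
    (1962/175/109 and 72/38/381).
    """
    records: List[TruthRecord] = []
    for label, counts, prefix in ((False, CURATED_TRUTH_COUNTS[0], "neg"),
                                  (True, CURATED_TRUTH_COUNTS[1], "pos")):
        for k, s in enumerate(_zone_scores(counts)):
            records.append(TruthRecord(
                variant_key=f"{prefix}_{k + 1:05d}", score=float(s),
                spliceogenic=label,
                region=representative_region(RegionCategory.OUTSIDE)))
    return records


def resampled_truth_dataset(seed: int = 0) -> List[TruthRecord]:
    """Zone counts fixed at the published values, scores resampled uniformly
    within each zone."""
    rng = np.random.default_rng(seed)
    zones = [(0.0, 0.1), (0.101, 0.199), (0.2, 1.0)]
    records: List[TruthRecord] = []
    for label, counts, prefix in ((False, CURATED_TRUTH_COUNTS[0], "neg"),
                                  (True, CURATED_TRUTH_COUNTS[1], "pos")):
        k = 0
        for (lo, hi), n in zip(zones, counts):
            for s in rng.uniform(lo, hi, size=n):
                k += 1
                records.append(TruthRecord(
                    variant_key=f"{prefix}_{k:05d}", score=float(s),
                    spliceogenic=label,
                    region=representative_region(RegionCategory.OUTSIDE)))
    return records


def generate_from_bin_probs(bin_edges: Sequence[float],
                            pos_probs: Sequence[float],
                            neg_probs: Sequence[float],
                            n_pos: int, n_neg: int,
                            seed: int = 0) -> Tuple[List[TruthRecord], np.ndarray]:
    """Sample scores with known within-bin class probabilities.

    Each record's bin is drawn from the class's bin-probability vector and
    its score uniformly within the bin, so the generating LR of bin *i* is
    exactly ``pos_probs[i] / neg_probs[i]``; that vector is returned
    alongside the records.
    """
    edges = np.asarray(bin_edges, dtype=float)
    pos_p = np.asarray(pos_probs, dtype=float)
    neg_p = np.asarray(neg_probs, dtype=float)
    if len(edges) != len(pos_p) + 1 or len(pos_p) != len(neg_p):
        raise ValueError("need len(bin_edges) == n_bins + 1 and matching prob vectors")
    if not (np.all(pos_p >= 0) and np.all(neg_p >= 0)):
        raise ValueError("bin probabilities must be non-negative")
    pos_p = pos_p / pos_p.sum()
    neg_p = neg_p / neg_p.sum()
    rng = np.random.default_rng(seed)
    records: List[TruthRecord] = []
    for label, n, p, prefix in ((True, n_pos, pos_p, "pos"), (False, n_neg, neg_p, "neg")):
        bins = rng.choice(len(p), size=n, p=p)
        lo = edges[bins]
        hi = edges[bins + 1]
        scores = rng.uniform(lo, hi)
        for k in range(n):
            records.append(TruthRecord(
                variant_key=f"{prefix}_{k + 1:05d}", score=float(scores[k]),
                spliceogenic=label,
                region=representative_region(RegionCategory.OUTSIDE)))
    true_lr = pos_p / neg_p
    return records, true_lr


def make_fixture_transcript(n_exons: int = 3, exon_len: int = 30,
                            intron_len: int = 60, strand: str = "+",
                            chrom: str = "chrT", start: int = 1001,
                            transcript_id: Optional[str] = None) -> TranscriptModel:
    """A deterministic multi-exon transcript for exhaustive region scans."""
    if n_exons < 2:
        raise ValueError("need at least 2 exons")
    if exon_len < 1 or intron_len < 1:
        raise ValueError("exon and intron lengths must be >= 1")
    exons = []
    pos = start
    for _ in range(n_exons):
        exons.append((pos, pos + exon_len - 1))
        pos += exon_len + intron_len
    tid = transcript_id or f"TX_{n_exons}x{exon_len}i{intron_len}{strand}"
    return TranscriptModel.from_genomic_exons(tid, chrom, strand, exons)
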