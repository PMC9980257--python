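"""Likelihood-ratio calibration of splice-prediction scores.

The core quantity is the diagnostic likelihood ratio of spliceogenicity for
a score bin,

    LR = (n_pos_in / n_pos_total) / (n_neg_in / n_neg_total),

i.e. the ratio of the in-bin proportions of spliceogenic and
non-spliceogenic variants in a curated truth set.  Its 95% interval uses
the standard log-method for diagnostic LRs (Simel et al. 1991):

    exp( ln LR +/- z * sqrt((1 - p_pos)/n_pos_in + (1 - p_neg)/n_neg_in) )

LRs map onto ACMG/AMP evidence strengths through the Bayesian
points-framework odds boundaries at a prior probability of pathogenicity
of 0.10: Very Strong 350, Strong 350**(1/2), Moderate 350**(1/4),
Supporting 350**(1/8); benign boundaries are the exact reciprocals.

Two surfaces are provided: plain functions (:func:`compute_lr`,
:func:`bin_dataset`, :func:`optimize_cutoffs`, ...) and a fitted-model pair
(:class:`SpliceScoreCalibration` / :class:`CalibrationResults`) in the
style of statsmodels, whose ``summary()`` prints the calibration table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .transcript import RegionClass, RegionCategory, Side

__all__ = [
    "TruthRecord", "BinCounts", "LRResult", "StrengthThresholds",
    "EvidenceStrength", "DegenerateInputError",
    "compute_lr", "map_lr_to_strength", "bin_dataset",
    "sensitivity_and_specificity", "optimize_cutoffs", "band_lrs",
    "stratified_calibration", "SpliceScoreCalibration", "CalibrationResults",
]


class DegenerateInputError(ValueError):
    """Raised when a computation is requested on an empty class or bin."""


class EvidenceStrength(Enum):
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"
    UNINFORMATIVE = "uninformative"
    SUPPORTING_BENIGN = "supporting_benign"
    MODERATE_BENIGN = "moderate_benign"
    STRONG_BENIGN = "strong_benign"
    VERY_STRONG_BENIGN = "very_strong_benign"


_PATHOGENIC_LADDER = [
    EvidenceStrength.VERY_STRONG,
    EvidenceStrength.STRONG,
    EvidenceStrength.MODERATE,
    EvidenceStrength.SUPPORTING,
]
_BENIGN_LADDER = [
    EvidenceStrength.VERY_STRONG_BENIGN,
    EvidenceStrength.STRONG_BENIGN,
    EvidenceStrength.MODERATE_BENIGN,
    EvidenceStrength.SUPPORTING_BENIGN,
]


@dataclass(frozen=True)
class StrengthThresholds:
    """Odds-of-pathogenicity boundaries for evidence strengths.

    Defaults are the Bayesian points-framework boundaries at prior 0.10
    (odds of pathogenicity 350 for Very Strong and its 1/2, 1/4 and 1/8
    exponential fractions).  Benign boundaries are the reciprocals.
    """

    prior: float = 0.10
    odds_very_strong: float = 350.0
    odds_strong: float = 350.0 ** 0.5
    odds_moderate: float = 350.0 ** 0.25
    odds_supporting: float = 350.0 ** 0.125

    def __post_init__(self) -> None:
        if not (0.0 < self.prior < 1.0):
            raise ValueError("prior must be in (0, 1)")
        if not (1.0 < self.odds_supporting < self.odds_moderate
                < self.odds_strong < self.odds_very_strong):
            raise ValueError("odds boundaries must satisfy 1 < supporting < moderate "
                             "< strong < very_strong")

    def pathogenic_bound(self, strength: EvidenceStrength) -> float:
        return {
            EvidenceStrength.VERY_STRONG: self.odds_very_strong,
            EvidenceStrength.STRONG: self.odds_strong,
            EvidenceStrength.MODERATE: self.odds_moderate,
            EvidenceStrength.SUPPORTING: self.odds_supporting,
        }[strength]

    def benign_bound(self, strength: EvidenceStrength) -> float:
        # benign categories are bounded by inverse odds
        return 1.0 / {
            EvidenceStrength.VERY_STRONG_BENIGN: self.odds_very_strong,
            EvidenceStrength.STRONG_BENIGN: self.odds_strong,
            EvidenceStrength.MODERATE_BENIGN: self.odds_moderate,
            EvidenceStrength.SUPPORTING_BENIGN: self.odds_supporting,
        }[strength]


DEFAULT_THRESHOLDS = StrengthThresholds()


@dataclass(frozen=True)
class TruthRecord:
    """One calibration observation: a variant with a score and a binary
    spliceogenicity label (intermediate/uninterpretable assay results are
    excluded upstream)."""

    variant_key: str
    score: float
    spliceogenic: bool
    region: RegionClass
    gene: Optional[str] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")


@dataclass(frozen=True)
class BinCounts:
    """2x2 counts behind one bin's likelihood ratio."""

    n_pos_in: int
    n_pos_total: int
    n_neg_in: int
    n_neg_total: int

    def __post_init__(self) -> None:
        if self.n_pos_total <= 0 or self.n_neg_total <= 0:
            raise DegenerateInputError("class totals must be positive")
        if not (0 <= self.n_pos_in <= self.n_pos_total):
            raise ValueError("n_pos_in must lie in [0, n_pos_total]")
        if not (0 <= self.n_neg_in <= self.n_neg_total):
            raise ValueError("n_neg_in must lie in [0, n_neg_total]")


@dataclass(frozen=True)
class LRResult:
    lr: float
    ci_low: float
    ci_high: float
    counts: BinCounts
    strength: EvidenceStrength
    continuity_corrected: bool = False
    defined: bool = True
    label: str = ""


def compute_lr(counts: BinCounts, z: float = 1.96,
               thresholds: StrengthThresholds = DEFAULT_THRESHOLDS,
               label: str = "") -> LRResult:
    """Likelihood ratio of spliceogenicity for one score bin, with log-method CI.

    A zero in-bin count in either class triggers a 0.5 continuity
    correction applied to all four cells (in/out for both classes); the
    result is flagged via ``continuity_corrected``.
    """
    npi, npt = float(counts.n_pos_in), float(counts.n_pos_total)
    nni, nnt = float(counts.n_neg_in), float(counts.n_neg_total)
    corrected = counts.n_pos_in == 0 or counts.n_neg_in == 0
    if corrected:
        npi, nni = npi + 0.5, nni + 0.5
        npt, nnt = npt + 1.0, nnt + 1.0
    p_pos = npi / npt
    p_neg = nni / nnt
    lr = p_pos / p_neg
    se = math.sqrt((1.0 - p_pos) / npi + (1.0 - p_neg) / nni)
    ci_low = math.exp(math.log(lr) - z * se)
    ci_high = math.exp(math.log(lr) + z * se)
    strength = map_lr_to_strength(lr, thresholds)
    return LRResult(lr=lr, ci_low=ci_low, ci_high=ci_high, counts=counts,
                    strength=strength, continuity_corrected=corrected, label=label)


def map_lr_to_strength(lr: float, thresholds: StrengthThresholds = DEFAULT_THRESHOLDS,
                       use_ci_bound: bool = False,
                       ci: Optional[Tuple[float, float]] = None) -> EvidenceStrength:
    """Map an LR to an ACMG/AMP evidence strength category.

    Pathogenic categories are inclusive at their lower odds boundary,
    benign categories at their upper (reciprocal) boundary; LRs strictly
    between the two Supporting boundaries are uninformative.  With
    ``use_ci_bound`` the conservative CI bound (lower bound on the
    pathogenic side, upper bound on the benign side) must clear the next
    weaker category's boundary, otherwise the strength is demoted one
    level (Supporting demotes to Uninformative, using 1.0 as its floor).
    """
    if lr < 0:
        raise ValueError("LR must be non-negative")
    if use_ci_bound and ci is None:
        raise ValueError("use_ci_bound requires a CI")

    if lr >= thresholds.odds_supporting:
        idx = next(i for i, cat in enumerate(_PATHOGENIC_LADDER)
                   if lr >= thresholds.pathogenic_bound(cat))
        cat = _PATHOGENIC_LADDER[idx]
        if use_ci_bound:
            next_bound = (thresholds.pathogenic_bound(_PATHOGENIC_LADDER[idx + 1])
                          if idx + 1 < len(_PATHOGENIC_LADDER) else 1.0)
            if ci[0] < next_bound:
                cat = (_PATHOGENIC_LADDER[idx + 1]
                       if idx + 1 < len(_PATHOGENIC_LADDER)
                       else EvidenceStrength.UNINFORMATIVE)
        return cat
    if lr <= 1.0 / thresholds.odds_supporting:
        idx = next(i for i, cat in enumerate(_BENIGN_LADDER)
                   if lr <= thresholds.benign_bound(cat))
        cat = _BENIGN_LADDER[idx]
        if use_ci_bound:
            next_bound = (thresholds.benign_bound(_BENIGN_LADDER[idx + 1])
                          if idx + 1 < len(_BENIGN_LADDER) else 1.0)
            if ci[1] > next_bound:
                cat = (_BENIGN_LADDER[idx + 1]
                       if idx + 1 < len(_BENIGN_LADDER)
                       else EvidenceStrength.UNINFORMATIVE)
        return cat
    return EvidenceStrength.UNINFORMATIVE


def _arrays(records: Iterable[TruthRecord]) -> Tuple[np.ndarray, np.ndarray]:
    recs = list(records)
    scores = np.array([r.score for r in recs], dtype=float)
    labels = np.array([bool(r.spliceogenic) for r in recs], dtype=bool)
    return scores, labels


def bin_dataset(records: Iterable[TruthRecord], low_cut: float,
                high_cut: float) -> Tuple[BinCounts, BinCounts, BinCounts]:
    """Partition records into (<= low), (between), (>= high) bins.

    The outer bins are closed at their cut-offs, matching the reporting
    convention '<=0.1 / >0.1 and <0.2 / >=0.2'.
    """
    if not (0.0 <= low_cut < high_cut <= 1.0):
        raise ValueError("require 0 <= low_cut < high_cut <= 1")
    scores, labels = _arrays(records)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("both classes must be represented")

    def cell(mask: np.ndarray) -> BinCounts:
        return BinCounts(n_pos_in=int((mask & labels).sum()), n_pos_total=n_pos,
                         n_neg_in=int((mask & ~labels).sum()), n_neg_total=n_neg)

    low = cell(scores <= low_cut)
    high = cell(scores >= high_cut)
    mid = cell((scores > low_cut) & (scores < high_cut))
    return low, mid, high


def sensitivity_and_specificity(records: Iterable[TruthRecord],
                                high_cut: float = 0.2,
                                low_cut: float = 0.1) -> Tuple[float, float]:
    """Sensitivity at the spliceogenic cut and specificity at the benign cut.

    sensitivity = spliceogenic records with score >= high_cut / all spliceogenic;
    specificity = non-spliceogenic records with score <= low_cut / all non-spliceogenic.
    """
    scores, labels = _arrays(records)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("both classes must be represented")
    sens = float((labels & (scores >= high_cut)).sum()) / n_pos
    spec = float((~labels & (scores <= low_cut)).sum()) / n_neg
    return sens, spec


def optimize_cutoffs(records: Iterable[TruthRecord], grid_step: float = 0.01,
                     objective_weights: Tuple[float, float, float] = (1.0, 1.0, 0.5),
                     ) -> Tuple[float, float, Dict[str, float]]:
    """Exhaustive grid search for the (low, high) cut-off pair.

    Minimizes ``w_fn * FN_rate + w_fp * FP_rate + w_uninf * uninf_fraction``
    where FN_rate is the fraction of spliceogenic records scoring <= low,
    FP_rate the fraction of non-spliceogenic records scoring >= high, and
    uninf_fraction the overall fraction of records strictly between the
    cuts.  The default down-weights the uninformative term to 0.5: an
    unclassified variant costs half a misclassified one, the usual
    reject-option condition (a rejection cost at or above the error cost
    makes the reject region degenerate).  Exact ties break toward the
    wider uninformative zone, then toward the smaller low cut.
    """
    scores, labels = _arrays(records)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos < 2 or n_neg < 2:
        raise DegenerateInputError("need at least 2 records per class")
    w_fn, w_fp, w_uninf = objective_weights
    n_steps = int(round(1.0 / grid_step))
    grid = np.round(np.arange(0, n_steps + 1) * grid_step, 10)
    if len(grid) < 2:
        raise ValueError("grid_step yields an empty cut-off grid")
    pos_sorted = np.sort(scores[labels])
    neg_sorted = np.sort(scores[~labels])
    n_all = n_pos + n_neg
    # counts at each grid point (<= c via side='right', < c via side='left')
    pos_le = np.searchsorted(pos_sorted, grid, side="right")
    neg_le = np.searchsorted(neg_sorted, grid, side="right")
    pos_lt = np.searchsorted(pos_sorted, grid, side="left")
    neg_lt = np.searchsorted(neg_sorted, grid, side="left")

    best = None
    best_key = None
    for i in range(len(grid) - 1):
        low = grid[i]
        fn_rate = pos_le[i] / n_pos
        for j in range(i + 1, len(grid)):
            high = grid[j]
            fp_rate = (n_neg - neg_lt[j]) / n_neg
            uninf = ((pos_lt[j] - pos_le[i]) + (neg_lt[j] - neg_le[i])) / n_all
            obj = w_fn * fn_rate + w_fp * fp_rate + w_uninf * uninf
            key = (obj, -(high - low), low)
            if best_key is None or obj < best_key[0] - 1e-12 or (
                    abs(obj - best_key[0]) <= 1e-12 and key[1:] < best_key[1:]):
                best_key = key
                best = (float(low), float(high),
                        {"fn_rate": float(fn_rate), "fp_rate": float(fp_rate),
                         "uninformative_fraction": float(uninf),
                         "objective": float(obj)})
    low, high, diag = best
    diag["n_pairs_evaluated"] = (len(grid) * (len(grid) - 1)) // 2
    return low, high, diag


def band_lrs(records: Iterable[TruthRecord],
             band_edges: Sequence[Tuple[float, float]],
             z: float = 1.96,
             thresholds: StrengthThresholds = DEFAULT_THRESHOLDS) -> List[LRResult]:
    """Per-band LRs for a set of non-overlapping score intervals.

    Bands are closed; a record falling on a shared edge is assigned to the
    first matching band.  A band containing no records in either class
    yields a flagged, undefined result (``defined=False``).
    """
    bands = [tuple(b) for b in band_edges]
    for (lo, hi) in bands:
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"invalid band ({lo}, {hi})")
    for (lo1, hi1), (lo2, hi2) in zip(sorted(bands), sorted(bands)[1:]):
        if lo2 < hi1:
            raise ValueError("bands must be non-overlapping")
    recs = list(records)
    scores, labels = _arrays(recs)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    assigned = np.full(len(recs), -1, dtype=int)
    for k, (lo, hi) in enumerate(bands):
        mask = (assigned == -1) & (scores >= lo) & (scores <= hi)
        assigned[mask] = k
    out: List[LRResult] = []
    for k, (lo, hi) in enumerate(bands):
        in_band = assigned == k
        npi = int((in_band & labels).sum())
        nni = int((in_band & ~labels).sum())
        label = f"[{lo}, {hi}]"
        if npi == 0 and nni == 0:
            counts = BinCounts(0, max(n_pos, 1), 0, max(n_neg, 1))
            out.append(LRResult(lr=float("nan"), ci_low=float("nan"),
                                ci_high=float("nan"), counts=counts,
                                strength=EvidenceStrength.UNINFORMATIVE,
                                defined=False, label=label))
        else:
            counts = BinCounts(npi, n_pos, nni, n_neg)
            out.append(compute_lr(counts, z=z, thresholds=thresholds, label=label))
    return out


def stratified_calibration(records: Iterable[TruthRecord],
                           low_cut: float = 0.1, high_cut: float = 0.2,
                           key: Optional[Callable[[TruthRecord], object]] = None,
                           strata: Optional[Sequence[object]] = None,
                           z: float = 1.96,
                           thresholds: StrengthThresholds = DEFAULT_THRESHOLDS,
                           ) -> Dict[object, Tuple[LRResult, LRResult, LRResult]]:
    """Per-stratum bin LRs at fixed cut-offs.

    ``key`` defaults to the record's region category.  If an explicit
    ``strata`` list is given, strata without records are skipped with a
    warning rather than raising.
    """
    if key is None:
        key = lambda r: r.region.category
    groups: Dict[object, List[TruthRecord]] = {}
    for r in records:
        groups.setdefault(key(r), []).append(r)
    wanted = list(strata) if strata is not None else list(groups)
    out: Dict[object, Tuple[LRResult, LRResult, LRResult]] = {}
    for s in wanted:
        recs = groups.get(s, [])
        if not recs:
            warnings.warn(f"stratum {s!r} has no records; skipped", stacklevel=2)
            continue
        try:
            low, mid, high = bin_dataset(recs, low_cut, high_cut)
        except DegenerateInputError as exc:
            warnings.warn(f"stratum {s!r} skipped: {exc}", stacklevel=2)
            continue
        out[s] = (compute_lr(low, z=z, thresholds=thresholds, label=f"<= {low_cut}"),
                  compute_lr(mid, z=z, thresholds=thresholds,
                             label=f"> {low_cut} and < {high_cut}"),
                  compute_lr(high, z=z, thresholds=thresholds, label=f">= {high_cut}"))
    return out


class SpliceScoreCalibration:
    """Calibration model for one prediction tool against a truth dataset.

    Parameters
    ----------
    records : sequence of TruthRecord
        The truth data: one score and spliceogenicity label per variant.
    thresholds : StrengthThresholds, optional
        Odds boundaries for the strength mapping (default: Bayesian
        points framework at prior 0.10).

    Examples
    --------
    >>> model = SpliceScoreCalibration(curated_truth_fixture())    # doctest: +SKIP
    >>> res = model.fit(low_cut=0.1, high_cut=0.2)          # doctest: +SKIP
    >>> print(res.summary())                                # doctest: +SKIP
    """

    def __init__(self, records: Iterable[TruthRecord],
                 thresholds: StrengthThresholds = DEFAULT_THRESHOLDS) -> None:
        self.records: Tuple[TruthRecord, ...] = tuple(records)
        if not self.records:
            raise DegenerateInputError("no records")
        self.thresholds = thresholds

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, score_col: str = "score",
                       label_col: str = "spliceogenic",
                       key_col: str = "variant_key",
                       gene_col: Optional[str] = "gene",
                       region_col: Optional[str] = "region",
                       source_col: Optional[str] = "source",
                       thresholds: StrengthThresholds = DEFAULT_THRESHOLDS,
                       ) -> "SpliceScoreCalibration":
        """Build a model from a tidy DataFrame (one row per variant)."""
        from .simulate import representative_region  # cycle-free late import
        records = []
        for _, row in df.iterrows():
            if region_col and region_col in df.columns and pd.notna(row[region_col]):
                region = representative_region(RegionCategory(str(row[region_col])))
            else:
                region = representative_region(RegionCategory.OUTSIDE)
            records.append(TruthRecord(
                variant_key=str(row[key_col]) if key_col in df.columns else f"rec_{_}",
                score=float(row[score_col]),
                spliceogenic=bool(int(row[label_col])),
                region=region,
                gene=(str(row[gene_col]) if gene_col and gene_col in df.columns
                      and pd.notna(row[gene_col]) else None),
                source=(str(row[source_col]) if source_col and source_col in df.columns
                        and pd.notna(row[source_col]) else None)))
        return cls(records, thresholds=thresholds)

    def fit(self, low_cut: float = 0.1, high_cut: float = 0.2,
            z: float = 1.96) -> "CalibrationResults":
        """Calibrate at fixed cut-offs; returns a results object."""
        low, mid, high = bin_dataset(self.records, low_cut, high_cut)
        lrs = (compute_lr(low, z=z, thresholds=self.thresholds, label=f"<={low_cut:g}"),
               compute_lr(mid, z=z, thresholds=self.thresholds,
                          label=f">{low_cut:g} and <{high_cut:g}"),
               compute_lr(high, z=z, thresholds=self.thresholds, label=f">={high_cut:g}"))
        sens, spec = sensitivity_and_specificity(self.records, high_cut=high_cut,
                                                 low_cut=low_cut)
        return CalibrationResults(model=self, low_cut=low_cut, high_cut=high_cut,
                                  z=z, bins=(low, mid, high), lrs=lrs,
                                  sensitivity=sens, specificity=spec)

    def fit_optimized(self, grid_step: float = 0.01,
                      objective_weights: Tuple[float, float, float] = (1.0, 1.0, 0.5),
                      z: float = 1.96) -> "CalibrationResults":
        """Search the cut-off grid, then calibrate at the optimum."""
        low_cut, high_cut, diag = optimize_cutoffs(self.records, grid_step=grid_step,
                                                   objective_weights=objective_weights)
        res = self.fit(low_cut=low_cut, high_cut=high_cut, z=z)
        res.diagnostics = diag
        return res


@dataclass
class CalibrationResults:
    """Results of a :class:`SpliceScoreCalibration` fit."""

    model: SpliceScoreCalibration
    low_cut: float
    high_cut: float
    z: float
    bins: Tuple[BinCounts, BinCounts, BinCounts]
    lrs: Tuple[LRResult, LRResult, LRResult]
    sensitivity: float
    specificity: float
    diagnostics: Optional[Dict[str, float]] = None

    _STRENGTH_DISPLAY = {
        EvidenceStrength.VERY_STRONG: "Very strong evidence (spliceogenicity)",
        EvidenceStrength.STRONG: "Strong evidence (spliceogenicity)",
        EvidenceStrength.MODERATE: "Moderate evidence (spliceogenicity)",
        EvidenceStrength.SUPPORTING: "Supporting evidence (spliceogenicity)",
        EvidenceStrength.UNINFORMATIVE: "Uninformative",
        EvidenceStrength.SUPPORTING_BENIGN: "Supporting evidence (non-spliceogenicity)",
        EvidenceStrength.MODERATE_BENIGN: "Moderate evidence (non-spliceogenicity)",
        EvidenceStrength.STRONG_BENIGN: "Strong evidence (non-spliceogenicity)",
        EvidenceStrength.VERY_STRONG_BENIGN: "Very strong evidence (non-spliceogenicity)",
    }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for counts, lr in zip(self.bins, self.lrs):
            rows.append({
                "score_bin": lr.label,
                "n_neg": counts.n_neg_in,
                "prop_neg": round(counts.n_neg_in / counts.n_neg_total, 2),
                "n_pos": counts.n_pos_in,
                "prop_pos": round(counts.n_pos_in / counts.n_pos_total, 2),
                "lr": round(lr.lr, 2),
                "ci_low": round(lr.ci_low, 2),
                "ci_high": round(lr.ci_high, 2),
                "evidence_strength": self._STRENGTH_DISPLAY[lr.strength],
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Splice-score calibration (likelihood ratios of spliceogenicity)",
            f"cut-offs: low <= {self.low_cut:g}, high >= {self.high_cut:g}; "
            f"prior = {self.model.thresholds.prior:g}; z = {self.z:g}",
            df.to_string(index=False),
            f"sensitivity at >= {self.high_cut:g}: {self.sensitivity:.0%}   "
            f"specificity at <= {self.low_cut:g}: {self.specificity:.0%}",
        ]
        if self.diagnostics:
            lines.append("cut-off search: " + ", ".join(
                f"{k}={v:.4g}" for k, v in self.diagnostics.items()))
        return "\n".join(lines)

    def band_lrs(self, band_edges: Sequence[Tuple[float, float]]) -> List[LRResult]:
        return band_lrs(self.model.records, band_edges, z=self.z,
                        thresholds=self.model.thresholds)

    def stratified(self, key: Optional[Callable[[TruthRecord], object]] = None,
                   strata: Optional[Sequence[object]] = None,
                   ) -> Dict[object, Tuple[LRResult, LRResult, LRResult]]:
        return stratified_calibration(self.model.records, low_cut=self.low_cut,
                                      high_cut=self.high_cut, key=key, strata=strata,
                                      z=self.z, thresholds=self.model.thresholds)
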