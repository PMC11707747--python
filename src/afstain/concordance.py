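"""Real-vs-virtual agreement statistics.

Two evaluation tracks:

* **H&E**: an external histologic-subtyping model segments nine
  categories at 10x (six LUAD tumor subtypes — acinar, cribriform,
  lepidic, micropapillary, papillary, solid — plus leukocyte aggregates,
  necrosis and "other").  Agreement between segmentations on real and
  virtual stains is the Dice score per category and case.  For non-LUAD
  cases the six subtypes merge into a single combined-tumor category, and
  per-subtype analyses can be restricted to LUAD cases where the subtype
  exceeds 5% of the total tumor area (LUAD-5%).  The subtyping network
  itself is consumed as label maps, not re-implemented.

* **mIF**: paired measurement sets (densities, percentages, TPS, CPS,
  colocalization) are summarized per measurement and ROI by Pearson's r
  with a Fisher-z 95% CI and the mean absolute difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import NormalDist

import numpy as np
from scipy import stats

from .quantify import MeasurementSet

TUMOR_SUBTYPES = (
    "acinar",
    "cribriform",
    "lepidic",
    "micropapillary",
    "papillary",
    "solid",
)
HE_CATEGORIES = TUMOR_SUBTYPES + ("leukocyte_aggregates", "necrosis", "other")
MERGED_CATEGORIES = ("combined_tumor", "leukocyte_aggregates", "necrosis", "other")

#: integer label vocabulary for 9-category maps
HE_LABELS = {name: i for i, name in enumerate(HE_CATEGORIES)}
MERGED_LABELS = {name: i for i, name in enumerate(MERGED_CATEGORIES)}


def dice_score(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a&b| / (|a| + |b|); empty-empty is defined as 1.0."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError("masks must have equal shape")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0  # both empty: perfect (vacuous) agreement
    return 2.0 * int((a & b).sum()) / denom


def merge_combined_tumor(label_map: np.ndarray) -> np.ndarray:
    """Collapse the six tumor subtypes into one combined-tumor label.

    Input uses the 9-category vocabulary; output the 4-category one.
    Pixel counts are conserved.
    """
    lm = np.asarray(label_map)
    if lm.min() < 0 or lm.max() >= len(HE_CATEGORIES):
        raise ValueError("label map contains ids outside the 9-category vocabulary")
    out = np.empty_like(lm)
    n_subtypes = len(TUMOR_SUBTYPES)
    tumor = lm < n_subtypes
    out[tumor] = MERGED_LABELS["combined_tumor"]
    for name in ("leukocyte_aggregates", "necrosis", "other"):
        out[lm == HE_LABELS[name]] = MERGED_LABELS[name]
    return out


def luad5_subset(cases: list[tuple], subtype: str) -> list:
    """Cases where ``subtype`` exceeds 5% of the total tumor area (strict).

    ``cases`` is a list of (case_id, {subtype: area}) tuples.  Cases with
    zero total tumor area are excluded with a warning.
    """
    import warnings

    if subtype not in TUMOR_SUBTYPES:
        raise ValueError(f"unknown tumor subtype {subtype!r}")
    kept = []
    for case_id, areas in cases:
        total = sum(areas.get(s, 0.0) for s in TUMOR_SUBTYPES)
        if total == 0:
            warnings.warn(f"case {case_id}: zero tumor area, excluded", stacklevel=2)
            continue
        if areas.get(subtype, 0.0) / total > 0.05:
            kept.append((case_id, areas))
    return kept


def pearson_ci(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Sample Pearson r with a Fisher z-transform confidence interval."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0:
        return r, r, r  # degenerate: the CI collapses
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zcrit = NormalDist().inv_cdf(1 - alpha / 2)
    return r, float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))


@dataclass
class ConcordanceEntry:
    measurement: str
    roi: str
    n_pairs: int
    n_dropped: int
    r: float | None
    ci_low: float | None
    ci_high: float | None
    mean_abs_diff: float


@dataclass
class ConcordanceReport:
    entries: list = field(default_factory=list)

    def entry(self, measurement: str, roi: str) -> ConcordanceEntry:
        for e in self.entries:
            if e.measurement == measurement and e.roi == roi:
                return e
        raise KeyError((measurement, roi))

    def to_records(self) -> list[dict]:
        return [vars(e) for e in self.entries]


def paired_summary(
    real: list[dict[str, MeasurementSet]],
    virtual: list[dict[str, MeasurementSet]],
) -> ConcordanceReport:
    """Per-measurement, per-ROI concordance between paired cases.

    ``real`` and ``virtual`` are parallel lists (one element per case) of
    {roi: MeasurementSet}.  Undefined entries are dropped pairwise and
    counted.  Order-invariant up to the pairing.
    """
    if len(real) != len(virtual) or len(real) == 0:
        raise ValueError("need equal-length, nonempty paired case lists")
    rois = sorted({roi for case in real for roi in case})
    report = ConcordanceReport()
    for roi in rois:
        keys = sorted(
            {
                k
                for case in real
                if roi in case
                for k in case[roi].values
                if case[roi].values[k] is not None
            }
        )
        for key in keys:
            xs, ys = [], []
            dropped = 0
            for rc, vc in zip(real, virtual):
                if roi not in rc or roi not in vc:
                    dropped += 1
                    continue
                rv = rc[roi].values.get(key)
                vv = vc[roi].values.get(key)
                if rv is None or vv is None:
                    dropped += 1
                    continue
                xs.append(float(rv))
                ys.append(float(vv))
            if not xs:
                continue
            x = np.array(xs)
            y = np.array(ys)
            mad = float(np.mean(np.abs(x - y)))
            if np.array_equal(x, y) and np.std(x) > 0:
                # exact agreement: report r = 1.0 without float jitter
                r, lo, hi = 1.0, 1.0, 1.0
            else:
                try:
                    r, lo, hi = pearson_ci(x, y)
                except ValueError:
                    r = lo = hi = None  # constant or too-short vectors
            report.entries.append(
                ConcordanceEntry(
                    measurement=key,
                    roi=roi,
                    n_pairs=len(xs),
                    n_dropped=dropped,
                    r=r,
                    ci_low=lo,
                    ci_high=hi,
                    mean_abs_diff=mad,
                )
            )
    return report
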