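"""Cross-library CDR3 enrichment detection by regression outlier analysis.

For one (baseline library, enriched sublibrary) pair and one chain, every
unique CDR3 amino-acid sequence is a point with its read count in the baseline
on X and in the enriched sublibrary on Y (a CDR3 absent from one library
enters with count 0).  After a variance-stabilizing transform of both axes
(Anscombe's 2·√(count + 3/8) by default; sqrt, log1p and identity are
available), an ordinary least squares line is fit; per-point externally
studentized residuals are tested against the t distribution with n − 3
degrees of freedom and Bonferroni-corrected across the n points.  Significant points above the
line are positively selected CDR3s, points below negatively selected —
the selection signal biopanning enrichment leaves on clone frequencies.

Polyreactivity summaries compare one baseline against several enriched
sublibraries: a CDR3 whose frequency rises in every sublibrary is flagged
polyreactive; positive selection within a named antigen subset marks
cross-reactivity candidates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import OLSInfluence

from .annotate import AnnotatedRearrangement

__all__ = [
    "CdrCountTable",
    "RegressionFit",
    "EnrichmentRecord",
    "count_cdr3",
    "fit_selection_regression",
    "detect_outliers",
    "enrichment_frame",
    "polyreactivity_flags",
]


@dataclass
class CdrCountTable:
    """Read counts per unique CDR3 amino-acid sequence for one library/chain.

    One CDR3 string is one clonotype; the total count equals the number of
    filtered reads that contributed.
    """

    library_id: str
    chain: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.counts.items() if v < 1}
        if bad:
            raise ValueError(f"counts must be >= 1 for present keys: {bad}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def get(self, cdr3: str) -> int:
        return self.counts.get(cdr3, 0)

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.counts.items())
        return pd.DataFrame({
            "library_id": self.library_id, "chain": self.chain,
            "cdr3": [k for k, _ in items], "count": [v for _, v in items]})


def count_cdr3(records: Iterable[AnnotatedRearrangement], library_id: str,
               chain: str) -> CdrCountTable:
    """Exact multiset counting of ``cdr3_aa`` over filtered records.

    Records must all pass the filter cascade and match ``chain``; the counts
    are the pair-level measure of CDR3 representation.
    """
    counter: Counter[str] = Counter()
    for rec in records:
        if rec.pass_filter is not True:
            raise ValueError(f"{rec.read_id}: record did not pass the filter")
        if rec.expected_chain != chain:
            raise ValueError(f"{rec.read_id}: chain {rec.expected_chain!r} != {chain!r}")
        if rec.cdr3_aa:
            counter[rec.cdr3_aa] += 1
    return CdrCountTable(library_id, chain, dict(counter))


_TRANSFORMS = {
    # Anscombe's variance-stabilizing transform for counts: the outlier test
    # assumes homoscedastic residuals, which raw or log1p counts violate
    "anscombe": lambda a: 2.0 * np.sqrt(np.asarray(a, dtype=float) + 0.375),
    "sqrt": np.sqrt,
    "log1p": np.log1p,
    "identity": lambda a: np.asarray(a, dtype=float),
}

DEFAULT_TRANSFORM = "anscombe"


@dataclass
class RegressionFit:
    """OLS fit of transformed enriched counts on transformed baseline counts."""

    baseline_id: str
    enriched_id: str
    chain: str
    transform: str
    cdr3s: list[str]
    baseline_counts: np.ndarray
    enriched_counts: np.ndarray
    x: np.ndarray
    y: np.ndarray
    slope: float
    intercept: float
    residuals: np.ndarray
    leverages: np.ndarray
    _results: object = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return len(self.cdr3s)


def fit_selection_regression(baseline: CdrCountTable, enriched: CdrCountTable,
                             transform: str = DEFAULT_TRANSFORM) -> RegressionFit:
    """Fit the per-pair selection regression over the union of CDR3 keys.

    Absent keys enter with count 0.  Raises when fewer than 3 CDR3s exist or
    when the baseline counts are all identical (degenerate X: the outlier
    geometry is meaningless).
    """
    if baseline.chain != enriched.chain:
        raise ValueError(f"chain mismatch: {baseline.chain!r} vs {enriched.chain!r}")
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; "
                         f"choose from {sorted(_TRANSFORMS)}")
    cdr3s = sorted(set(baseline.counts) | set(enriched.counts))
    if len(cdr3s) < 3:
        raise ValueError(f"need >= 3 CDR3s, got {len(cdr3s)}")
    b = np.array([baseline.get(k) for k in cdr3s], dtype=float)
    e = np.array([enriched.get(k) for k in cdr3s], dtype=float)
    if np.all(b == b[0]):
        raise ValueError("degenerate baseline: all counts identical, "
                         "regression not meaningful")
    fn = _TRANSFORMS[transform]
    x, y = fn(b), fn(e)
    results = sm.OLS(y, sm.add_constant(x)).fit()
    influence = OLSInfluence(results)
    return RegressionFit(
        baseline_id=baseline.library_id, enriched_id=enriched.library_id,
        chain=baseline.chain, transform=transform, cdr3s=cdr3s,
        baseline_counts=b.astype(int), enriched_counts=e.astype(int),
        x=x, y=y, slope=float(results.params[1]),
        intercept=float(results.params[0]),
        residuals=np.asarray(results.resid),
        leverages=np.asarray(influence.hat_matrix_diag),
        _results=results)


@dataclass
class EnrichmentRecord:
    """Per-CDR3 outlier statistics and selection label for one library pair."""

    cdr3: str
    baseline_count: int
    enriched_count: int
    x: float
    y: float
    studentized_residual: float
    bonferroni_p: float
    label: str  # "positive", "negative" or "none"


def detect_outliers(fit: RegressionFit, alpha: float = 0.05) -> list[EnrichmentRecord]:
    """Label significant regression outliers as positive/negative selection.

    Externally studentized residuals are compared with the t distribution on
    n − 3 degrees of freedom (n points, two regression parameters, one point
    held out); two-sided p-values are Bonferroni-corrected by n.  A point is
    labeled by the sign of its residual iff its corrected p is below
    ``alpha`` — above the line means positive selection.
    """
    n = fit.n
    dof = n - 3
    if dof <= 0:
        raise ValueError(f"need > 3 points for outlier testing, got {n}")
    influence = OLSInfluence(fit._results)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_ext = np.asarray(influence.resid_studentized_external)
    # an exact fit gives 0/0 (or rounding dust); a zero residual is no outlier
    r_ext = np.where(np.isfinite(r_ext), r_ext, 0.0)
    noise_floor = 1e-10 * max(1.0, float(np.max(np.abs(fit.y))))
    r_ext = np.where(np.abs(fit.residuals) <= noise_floor, 0.0, r_ext)
    p = 2.0 * stats.t.sf(np.abs(r_ext), dof)
    bonf = np.minimum(1.0, p * n)
    out: list[EnrichmentRecord] = []
    for i, cdr3 in enumerate(fit.cdr3s):
        if bonf[i] < alpha:
            label = "positive" if r_ext[i] > 0 else "negative"
        else:
            label = "none"
        out.append(EnrichmentRecord(
            cdr3=cdr3, baseline_count=int(fit.baseline_counts[i]),
            enriched_count=int(fit.enriched_counts[i]), x=float(fit.x[i]),
            y=float(fit.y[i]), studentized_residual=float(r_ext[i]),
            bonferroni_p=float(bonf[i]), label=label))
    return out


def enrichment_frame(records: Sequence[EnrichmentRecord], chain: str) -> pd.DataFrame:
    """Tabular (machine-readable scatter) view of one pair's outlier analysis."""
    return pd.DataFrame({
        "cdr3": [r.cdr3 for r in records],
        "chain": chain,
        "baseline_count": [r.baseline_count for r in records],
        "enriched_count": [r.enriched_count for r in records],
        "studentized_residual": [r.studentized_residual for r in records],
        "bonferroni_p": [r.bonferroni_p for r in records],
        "label": [r.label for r in records]})


def polyreactivity_flags(results: Mapping[str, Sequence[EnrichmentRecord]],
                         cross_reactive_subset: Sequence[str] = (),
                         ) -> pd.DataFrame:
    """Summarize selection of each CDR3 across several enriched sublibraries.

    ``results`` maps a sublibrary name to the enrichment records of its
    (shared baseline, sublibrary) pair.  Per CDR3 the summary reports in how
    many sublibraries it was positively selected and in how many its
    normalized frequency increased over the baseline; a CDR3 increased in
    *all* provided sublibraries is flagged polyreactive.  When
    ``cross_reactive_subset`` names sublibraries, a CDR3 positively selected
    in every one of them is additionally flagged a cross-reactivity candidate.

    Raises when the per-pair baselines disagree (different baseline counts
    for a shared CDR3).
    """
    if len(results) < 2:
        raise ValueError("need >= 2 sublibrary result sets")
    missing = set(cross_reactive_subset) - set(results)
    if missing:
        raise ValueError(f"cross-reactive subset names unknown libraries: "
                         f"{sorted(missing)}")

    baseline_counts: dict[str, int] = {}
    baseline_totals: dict[str, int] = {}
    per_lib: dict[str, dict[str, EnrichmentRecord]] = {}
    for lib, recs in results.items():
        per_lib[lib] = {r.cdr3: r for r in recs}
        baseline_totals[lib] = sum(r.baseline_count for r in recs)
        for r in recs:
            if r.cdr3 in baseline_counts and baseline_counts[r.cdr3] != r.baseline_count:
                raise ValueError(
                    f"inconsistent baselines: CDR3 {r.cdr3!r} has baseline "
                    f"count {baseline_counts[r.cdr3]} vs {r.baseline_count}")
            baseline_counts[r.cdr3] = r.baseline_count
    totals = set(baseline_totals.values())
    if len(totals) != 1:
        raise ValueError(f"inconsistent baseline totals across pairs: "
                         f"{baseline_totals}")
    baseline_total = totals.pop()

    libs = list(results)
    enriched_totals = {lib: sum(r.enriched_count for r in results[lib])
                       for lib in libs}
    rows = []
    for cdr3 in sorted(baseline_counts):
        base_freq = baseline_counts[cdr3] / baseline_total
        positive_in, increased_in = [], []
        for lib in libs:
            rec = per_lib[lib].get(cdr3)
            if rec is None:
                continue
            if rec.label == "positive":
                positive_in.append(lib)
            enr_total = enriched_totals[lib]
            if enr_total and rec.enriched_count / enr_total > base_freq:
                increased_in.append(lib)
        rows.append({
            "cdr3": cdr3,
            "baseline_count": baseline_counts[cdr3],
            "n_positive": len(positive_in),
            "positive_in": ",".join(positive_in),
            "n_increased": len(increased_in),
            "polyreactive": len(increased_in) == len(libs),
            "cross_reactive_candidate": bool(cross_reactive_subset) and
                all(lib in positive_in for lib in cross_reactive_subset)})
    return pd.DataFrame(rows)
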