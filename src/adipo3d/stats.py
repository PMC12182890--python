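"""Group-level statistics for adipocyte feature tables.

Group summaries are reported as mean ± SEM with the pooled per-adipocyte n
(SEM = sd/√n over all cells of the group).  Two-group comparisons use the
Mann–Whitney U test; binned class distributions are compared bin-by-bin
with multiple Mann–Whitney tests corrected by a false-discovery-rate
step-up at Q = 5% (two-stage step-up by default, matching the convention
of common GraphPad-style analysis software; the standard step-up is
available as an option).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

from .volumes import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "StudyDesign",
    "BinSpec",
    "default_bin_specs",
    "SummaryError",
    "percent_difference",
    "mann_whitney",
    "group_summary",
    "binned_distribution",
    "fdr_stepup",
    "multiple_mw_fdr",
]


class SummaryError(ParameterError):
    """Group summary cannot be computed (e.g. a group with < 2 observations)."""


@dataclass(frozen=True)
class StudyDesign:
    """Group × sample × cell layout of a study."""

    groups: tuple[str, ...] = ("healthy", "obese")
    samples_per_group: int = 3
    cells_per_sample: int = 450

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))

    def validate(self) -> None:
        if len(self.groups) < 1 or len(set(self.groups)) != len(self.groups):
            raise ParameterError("groups must be non-empty and unique")
        if self.samples_per_group < 1 or self.cells_per_sample < 1:
            raise ParameterError("counts must be >= 1")

    @property
    def cells_per_group(self) -> int:
        return self.samples_per_group * self.cells_per_sample


@dataclass(frozen=True)
class BinSpec:
    """Uniform class bins for one feature's distribution analysis."""

    feature: str
    edges: tuple[float, ...]

    def __post_init__(self):
        edges = tuple(float(e) for e in self.edges)
        if len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ParameterError("edges must be strictly increasing, length >= 2")
        object.__setattr__(self, "edges", edges)


def default_bin_specs() -> dict[str, BinSpec]:
    """Default class bins: 50,000 µm³ volume classes, 5 µm NOD classes,
    10 µm diameter classes, 0.04 sphericity classes."""
    return {
        "volume_um3": BinSpec("volume_um3", tuple(np.arange(0.0, 1_000_001.0, 50_000.0))),
        "nod_um": BinSpec("nod_um", tuple(np.arange(0.0, 151.0, 5.0))),
        "equivalent_diameter_um": BinSpec(
            "equivalent_diameter_um", tuple(np.arange(0.0, 201.0, 10.0))
        ),
        "sphericity": BinSpec("sphericity", tuple(np.round(np.arange(0.0, 1.041, 0.04), 3))),
    }


def percent_difference(reference_mean: float, other_mean: float) -> float:
    """Percent change of ``other_mean`` relative to ``reference_mean``."""
    if reference_mean == 0:
        raise ParameterError("reference mean must be nonzero")
    return 100.0 * (other_mean - reference_mean) / reference_mean


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Returns ``(U, p)`` where U is the rank-sum statistic of the first
    sample with midrank tie handling.  The p-value is exact (full
    enumeration of rank assignments) when n1+n2 <= 12 and there are no
    ties, else a normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = spstats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


DEFAULT_FEATURES = ("volume_um3", "nod_um", "equivalent_diameter_um", "sphericity")


def group_summary(
    features: pd.DataFrame,
    design: StudyDesign | None = None,
    feature_names=DEFAULT_FEATURES,
) -> pd.DataFrame:
    """Per-feature per-group mean, SEM and n, with Mann–Whitney p-values.

    ``features`` must carry a ``group`` column; NaN feature values are
    dropped per feature.  SEM uses the pooled per-adipocyte n of each
    group.  For exactly two groups a two-sided Mann–Whitney test compares
    them; with any other number of groups U and p are NaN.
    """
    if "group" not in features.columns:
        raise SummaryError("feature table must carry a 'group' column")
    groups = design.groups if design is not None else tuple(pd.unique(features["group"]))
    rows = []
    for feat in feature_names:
        if feat not in features.columns:
            continue
        per_group = {}
        for g in groups:
            vals = features.loc[features["group"] == g, feat].dropna().to_numpy()
            if vals.size < 2:
                raise SummaryError(
                    f"group {g!r} has {vals.size} observation(s) for {feat!r}; need >= 2"
                )
            per_group[g] = vals
        if len(groups) == 2:
            u, p = mann_whitney(per_group[groups[0]], per_group[groups[1]])
        else:
            u, p = np.nan, np.nan
        for g in groups:
            vals = per_group[g]
            rows.append(
                {
                    "feature": feat,
                    "group": g,
                    "n": int(vals.size),
                    "mean": float(vals.mean()),
                    "sem": float(vals.std(ddof=1) / np.sqrt(vals.size)),
                    "U": u,
                    "p_value": p,
                    "significant_p05": bool(p < 0.05) if np.isfinite(p) else False,
                }
            )
    return pd.DataFrame(rows)


def _histogram(values: np.ndarray, edges: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Left-closed/right-open histogram (last bin closed) with under/overflow
    bins appended only when data fall outside the spec'd range."""
    counts, _ = np.histogram(values, bins=edges)
    labels = [f"[{lo:g}, {hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
    labels[-1] = labels[-1][:-1] + "]"
    under = int(np.sum(values < edges[0]))
    over = int(np.sum(values > edges[-1]))
    if under:
        counts = np.concatenate([[under], counts])
        labels = [f"(-inf, {edges[0]:g})"] + labels
    if over:
        counts = np.concatenate([counts, [over]])
        labels = labels + [f"({edges[-1]:g}, inf)"]
    return counts, labels


def binned_distribution(
    features: pd.DataFrame,
    spec: BinSpec,
    design: StudyDesign | None = None,
    q_value: float = 0.05,
    fdr_method: str = "two_stage",
) -> pd.DataFrame:
    """Class-distribution table for one feature.

    Per-sample histograms over the spec'd bins (overflow/underflow bins
    appended when needed), per-group mean count per bin, and — for two
    groups — a per-bin Mann–Whitney test across the per-sample counts,
    FDR-corrected at ``q_value``.
    """
    if not {"group", "sample_id"} <= set(features.columns):
        raise ParameterError("feature table needs 'group' and 'sample_id' columns")
    edges = np.asarray(spec.edges, dtype=float)
    groups = design.groups if design is not None else tuple(pd.unique(features["group"]))

    # union of bin labels over all samples (under/overflow may differ)
    all_vals = features[spec.feature].dropna().to_numpy()
    _, bin_labels = _histogram(all_vals, edges)
    per_sample: dict[tuple[str, str], np.ndarray] = {}
    for (g, s), sub in features.groupby(["group", "sample_id"], sort=True):
        vals = sub[spec.feature].dropna().to_numpy()
        counts, labels = _histogram(vals, edges)
        aligned = np.zeros(len(bin_labels))
        for c, lab in zip(counts, labels):
            aligned[bin_labels.index(lab)] = c
        per_sample[(g, s)] = aligned

    table = pd.DataFrame({"bin": bin_labels, "feature": spec.feature})
    for g in groups:
        stack = np.array([v for (gg, _), v in per_sample.items() if gg == g])
        table[f"mean_count_{g}"] = stack.mean(axis=0) if len(stack) else 0.0

    ga = [v for (g, _), v in per_sample.items() if g == groups[0]]
    gb = [v for (g, _), v in per_sample.items() if g == groups[-1]]
    if len(groups) == 2 and ga and gb:
        xa, xb = np.array(ga), np.array(gb)
        res = multiple_mw_fdr(
            [xa[:, i] for i in range(xa.shape[1])],
            [xb[:, i] for i in range(xb.shape[1])],
            q=q_value,
            method=fdr_method,
        )
        table["p_value"] = res["p_value"].to_numpy()
        table["q_value"] = res["q_value"].to_numpy()
        table["discovery"] = res["discovery"].to_numpy()
    return table


def fdr_stepup(pvalues, q: float = 0.05, method: str = "two_stage"):
    """False-discovery-rate step-up over a vector of p-values.

    ``method="two_stage"`` is the two-stage step-up (Benjamini–Krieger–
    Yekutieli); ``"standard"`` is the classic Benjamini–Hochberg step-up.

    Returns
    -------
    (reject, qvalues) : (ndarray of bool, ndarray of float)
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    sm_method = {"two_stage": "fdr_tsbky", "standard": "fdr_bh"}.get(method)
    if sm_method is None:
        raise ParameterError(f"unknown FDR method {method!r}")
    reject, qvals, _, _ = multipletests(p, alpha=q, method=sm_method)
    return reject, qvals


def multiple_mw_fdr(
    samples_x, samples_y, q: float = 0.05, method: str = "two_stage"
) -> pd.DataFrame:
    """Per-bin Mann–Whitney tests with FDR step-up correction at level ``q``.

    ``samples_x``/``samples_y`` are parallel lists of per-bin observation
    vectors (e.g. per-sample class counts for the two groups).  Bins empty
    in either group are skipped (logged) and reported with NaN p/q.
    """
    if len(samples_x) != len(samples_y):
        raise ParameterError("samples_x and samples_y must have the same length")
    n_bins = len(samples_x)
    if n_bins == 0:
        raise ParameterError("need at least one bin")
    pvals = np.full(n_bins, np.nan)
    for i, (xa, xb) in enumerate(zip(samples_x, samples_y)):
        xa = np.asarray(xa, dtype=float)
        xb = np.asarray(xb, dtype=float)
        if xa.size == 0 or xb.size == 0:
            logger.info("bin %d empty in one group; skipped from FDR", i)
            continue
        _, pvals[i] = mann_whitney(xa, xb)
    tested = np.isfinite(pvals)
    qvals = np.full(n_bins, np.nan)
    reject = np.zeros(n_bins, dtype=bool)
    if tested.any():
        r, qv = fdr_stepup(pvals[tested], q=q, method=method)
        qvals[tested] = qv
        reject[tested] = r
    return pd.DataFrame({"p_value": pvals, "q_value": qvals, "discovery": reject})
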