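"""Cell-composition deconvolution and progression-CpG discovery.

Bulk CLL samples are mixtures of leukemic B cells and residual normal
mononuclear cells, so raw 450k beta values confound tumor-intrinsic
methylation change with shifts in cellular composition.  This module

1. estimates per-sample mixing proportions of five cell types
   (B, NK, CD4+ T, CD8+ T, Neutrophil) by constrained least squares
   against a reference panel of cell-type-specific marker CpGs;
2. regresses composition out of every CpG (OLS on the proportions,
   keeping the grand mean plus the residual);
3. scores per-patient change in B-cell load and cumulative methylation
   deviation; and
4. discovers progression-associated CpGs with a paired two-sided Wilcoxon
   signed-rank test across patients (t1 vs t2), BH-FDR corrected.

Beta values are methylation fractions in [0, 1]; a "delta" is always
t2 minus t1 on that scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .somatic import bh_fdr

CELL_TYPES = ("B", "NK", "CD4T", "CD8T", "Neutrophil")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ReferencePanel:
    """Marker-CpG x cell-type matrix of mean reference betas."""

    profiles: pd.DataFrame  # index: marker cpg ids; columns: CELL_TYPES

    def __post_init__(self) -> None:
        missing = [c for c in CELL_TYPES if c not in self.profiles.columns]
        if missing:
            raise ValueError(f"reference panel missing cell types: {missing}")
        self.profiles = self.profiles[list(CELL_TYPES)]
        if len(self.profiles) < 1:
            raise ValueError("reference panel needs at least one marker CpG")
        vals = self.profiles.to_numpy()
        if np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any():
            raise ValueError("reference betas must lie in [0, 1]")

    @property
    def marker_ids(self) -> pd.Index:
        return self.profiles.index


@dataclass
class BetaMatrix:
    """CpG x sample beta matrix plus per-sample metadata.

    ``metadata`` is indexed by sample id and carries ``patient_id``,
    ``timepoint`` (``t1``/``t2``) and optionally ``sorted_flag``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        vals = self.values.to_numpy()
        if vals.size and ((vals < -1e-9) | (vals > 1 + 1e-9)).any():
            raise ValueError("beta values must lie in [0, 1]")
        if len(self.metadata):
            extra = set(self.values.columns) - set(self.metadata.index)
            if extra:
                raise ValueError(f"samples without metadata: {sorted(extra)}")

    def paired(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (t1, t2) frames with one column per patient, aligned.

        Every patient must contribute exactly one t1 and one t2 sample.
        """
        meta = self.metadata.loc[list(self.values.columns)]
        t1_map, t2_map = {}, {}
        for sample, row in meta.iterrows():
            tp = str(row["timepoint"])
            target = t1_map if tp == "t1" else t2_map if tp == "t2" else None
            if target is None:
                raise ValueError(f"unknown timepoint {tp!r} for sample {sample}")
            if row["patient_id"] in target:
                raise ValueError(f"patient {row['patient_id']} has multiple {tp} samples")
            target[row["patient_id"]] = sample
        patients = sorted(t1_map)
        if sorted(t2_map) != patients:
            raise ValueError("every patient needs exactly one t1 and one t2 sample")
        t1 = self.values[[t1_map[p] for p in patients]].set_axis(patients, axis=1)
        t2 = self.values[[t2_map[p] for p in patients]].set_axis(patients, axis=1)
        return t1, t2

    def paired_deltas(self) -> pd.DataFrame:
        """CpG x patient frame of t2 - t1 beta changes."""
        t1, t2 = self.paired()
        return t2 - t1


# ---------------------------------------------------------------------------
# deconvolution
# ---------------------------------------------------------------------------

def _simplex_lstsq(R: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact solution of min ||R w - b||^2 s.t. w >= 0, sum w = 1.

    Enumerates every support of the (small) simplex, solves the
    equality-constrained KKT system on each, and keeps the feasible
    solution with the smallest residual.  Exact for k up to ~15; here k=5.
    """
    m, k = R.shape
    best_w, best_r = None, np.inf
    for size in range(1, k + 1):
        for support in combinations(range(k), size):
            Rs = R[:, support]
            G = 2.0 * (Rs.T @ Rs)
            kkt = np.zeros((size + 1, size + 1))
            kkt[:size, :size] = G
            kkt[:size, size] = 1.0
            kkt[size, :size] = 1.0
            rhs = np.concatenate([2.0 * (Rs.T @ b), [1.0]])
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                continue
            w = sol[:size]
            if (w < -1e-9).any():
                continue
            resid = float(np.sum((Rs @ w - b) ** 2))
            if resid < best_r - 1e-15:
                best_r = resid
                best_w = np.zeros(k)
                best_w[list(support)] = np.clip(w, 0.0, None)
    if best_w is None:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError("no feasible simplex solution found")
    return best_w / best_w.sum()


def deconvolve(beta, panel: ReferencePanel) -> np.ndarray:
    """Estimate 5-cell-type proportions for one sample.

    ``beta`` is a Series (or mapping) of betas covering every marker CpG of
    the panel.  Solves constrained least squares on the marker x cell-type
    reference matrix; the result is non-negative and sums to one.
    """
    beta = pd.Series(beta, dtype=float)
    missing = panel.marker_ids.difference(beta.index)
    if len(missing):
        raise ValueError(f"sample is missing marker CpGs: {list(missing[:10])}"
                         + ("..." if len(missing) > 10 else ""))
    R = panel.profiles.to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < R.shape[1]:
        raise ValueError("reference matrix is rank-deficient; "
                         "cell types are not distinguishable")
    b = beta.loc[panel.marker_ids].to_numpy(dtype=float)
    return _simplex_lstsq(R, b)


def deconvolve_samples(betas: pd.DataFrame, panel: ReferencePanel) -> pd.DataFrame:
    """Per-sample composition estimates (samples x cell types)."""
    rows = {s: deconvolve(betas[s], panel) for s in betas.columns}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(CELL_TYPES))


# ---------------------------------------------------------------------------
# composition adjustment
# ---------------------------------------------------------------------------

def adjust_for_composition(
    betas: pd.DataFrame,
    compositions: pd.DataFrame,
    drop: str = "Neutrophil",
) -> pd.DataFrame:
    """Regress cell-type composition out of every CpG.

    Per CpG, betas are regressed (OLS, across samples) on an intercept plus
    four of the five proportions (``drop`` is omitted because the five sum
    to one); the adjusted value is the CpG's grand mean plus the residual,
    clamped to [0, 1].  Samples with identical compositions are returned
    unchanged (the regression explains nothing).
    """
    samples = list(betas.columns)
    missing = [s for s in samples if s not in compositions.index]
    if missing:
        raise ValueError(f"no composition estimate for samples: {missing}")
    comp = compositions.loc[samples]
    sums = comp[list(CELL_TYPES)].sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        bad = list(comp.index[~np.isclose(sums, 1.0, atol=1e-6)])
        raise ValueError(f"composition rows must sum to 1; offending samples: {bad}")

    predictors = [c for c in CELL_TYPES if c != drop]
    X = np.column_stack([np.ones(len(samples)), comp[predictors].to_numpy(float)])
    if X.shape[0] <= X.shape[1]:
        raise ValueError(f"need more than {X.shape[1]} samples to adjust for "
                         "composition")
    Y = betas.to_numpy(float).T  # samples x cpgs
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    grand_mean = Y.mean(axis=0)
    adjusted = np.clip(grand_mean[None, :] + resid, 0.0, 1.0).T
    return pd.DataFrame(adjusted, index=betas.index, columns=betas.columns)


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def b_cell_orientation(panel: ReferencePanel, sites: Iterable[str]) -> pd.Series:
    """Per-site sign (+1/-1) so that rising B-cell load raises the score.

    A site hypermethylated in B cells relative to the mean of the other
    four types gets +1, a hypomethylated one -1.
    """
    sites = list(sites)
    prof = panel.profiles.loc[sites]
    others = [c for c in CELL_TYPES if c != "B"]
    diff = prof["B"] - prof[others].mean(axis=1)
    return pd.Series(np.where(diff >= 0, 1.0, -1.0), index=sites)


def b_cell_score(
    betas_t1: pd.Series,
    betas_t2: pd.Series,
    b_cell_sites: Iterable[str],
    orientation: pd.Series | None = None,
) -> float:
    """Mean signed beta change over B-cell-specific sites.

    With ``orientation`` (from :func:`b_cell_orientation`) each site's change
    is flipped so that an increase in B-cell (leukemia) load always pushes
    the score up; without it the raw mean change is returned.
    """
    sites = list(b_cell_sites)
    if not sites:
        raise ValueError("b_cell_score needs a non-empty site set")
    delta = (pd.Series(betas_t2) - pd.Series(betas_t1)).loc[sites]
    if delta.isna().any():
        raise ValueError("sites missing from one of the beta vectors")
    if orientation is not None:
        delta = delta * pd.Series(orientation).loc[sites]
    return float(delta.mean())


def progression_score(
    betas_t1: pd.Series,
    betas_t2: pd.Series,
    progression_cpgs: Iterable[str],
) -> float:
    """Cumulative methylation deviation: sum of |delta| over the
    progression-associated CpGs."""
    sites = list(progression_cpgs)
    if not sites:
        warnings.warn("empty progression CpG set; score is 0", stacklevel=2)
        return 0.0
    delta = (pd.Series(betas_t2) - pd.Series(betas_t1)).loc[sites]
    if delta.isna().any():
        raise ValueError("sites missing from one of the beta vectors")
    return float(delta.abs().sum())


# ---------------------------------------------------------------------------
# paired progression testing
# ---------------------------------------------------------------------------

def signed_rank_test(diffs, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p-value for one CpG's paired deltas.

    Zero differences are dropped (signed-rank convention).  The exact null
    distribution is used when the non-zero sample is small (n <=
    ``exact_max_n``) and has no tied magnitudes; otherwise the normal
    approximation with continuity correction and average ranks is used.
    Returns 1.0 when every difference is zero.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[~np.isnan(d)]
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    magnitudes = np.abs(d)
    exact_ok = d.size <= exact_max_n and np.unique(magnitudes).size == d.size
    if exact_ok:
        return float(stats.wilcoxon(d, method="exact").pvalue)
    return float(stats.wilcoxon(d, method="approx", correction=True).pvalue)


def paired_progression_test(
    betas: BetaMatrix,
    fdr: float = 0.05,
    min_pairs: int = 6,
) -> pd.DataFrame:
    """Discover progression-associated CpGs by paired testing across patients.

    For each CpG the per-patient (t1, t2) betas are paired and the two-sided
    signed-rank test applied to the deltas.  CpGs with fewer than
    ``min_pairs`` complete pairs, or with all-zero deltas, are flagged
    ``untested`` (p = 1, q = NaN).  BH-FDR runs over the tested CpGs;
    ``significant`` means q < ``fdr``; ``direction`` is the sign of the
    median paired delta.
    """
    deltas = betas.paired_deltas()
    n_complete = deltas.notna().sum(axis=1)
    med = deltas.median(axis=1)

    p_values = np.ones(len(deltas))
    untested = np.zeros(len(deltas), dtype=bool)
    arr = deltas.to_numpy(float)
    for i in range(arr.shape[0]):
        d = arr[i]
        d = d[~np.isnan(d)]
        if d.size < min_pairs or not np.any(d != 0.0):
            untested[i] = True
            continue
        p_values[i] = signed_rank_test(d)

    q = np.full(len(deltas), np.nan)
    tested = ~untested
    if tested.any():
        q[tested] = bh_fdr(p_values[tested])
    direction = np.select([med > 0, med < 0], ["up", "down"], default="none")
    out = pd.DataFrame({
        "cpg_id": deltas.index,
        "n_pairs": n_complete.to_numpy(),
        "median_paired_delta": med.to_numpy(),
        "wilcoxon_p": p_values,
        "q_value": q,
        "direction": direction,
        "untested": untested,
    })
    out["significant"] = (out["q_value"] < fdr).fillna(False)
    return out


# ---------------------------------------------------------------------------
# change-magnitude and sorted-cell summaries
# ---------------------------------------------------------------------------

def change_magnitude_summary(
    deltas: pd.DataFrame,
    thresholds: tuple[float, ...] = (0.05, 0.20),
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-patient counts of CpGs whose |delta| exceeds each threshold.

    ``deltas`` is CpG x patient (e.g. :meth:`BetaMatrix.paired_deltas` on
    adjusted betas).  Returns the per-patient table and the cohort means.
    """
    per_patient = pd.DataFrame(index=deltas.columns)
    for thr in thresholds:
        per_patient[f"n_above_{thr:g}"] = (deltas.abs() > thr).sum(axis=0)
    return per_patient, per_patient.mean(axis=0)


def quantile_change_enrichment(
    mean_deltas: pd.Series,
    sets: Mapping[str, Iterable[str]],
    q: float = 0.05,
) -> pd.DataFrame:
    """Enrichment of CpG sets among the most-changing CpGs.

    Flags CpGs in the top and bottom ``q`` quantiles of ``mean_deltas``
    (mean methylation change, e.g. averaged over sorted-cell sample pairs)
    and tests each named set for association with the flag via a 2x2 Fisher
    exact test.  OR = (a*d)/(b*c); degenerate margins yield OR = NaN.
    """
    if not (0 < q <= 0.5):
        raise ValueError("q must lie in (0, 0.5]")
    lo = mean_deltas.quantile(q)
    hi = mean_deltas.quantile(1 - q)
    flagged = (mean_deltas <= lo) | (mean_deltas >= hi)
    records = []
    for name, members in sets.items():
        member = mean_deltas.index.isin(set(members))
        a = int((flagged & member).sum())
        b = int((flagged & ~member).sum())
        c = int((~flagged & member).sum())
        d = int((~flagged & ~member).sum())
        odds = (a * d) / (b * c) if b * c > 0 else float("nan")
        p = float(stats.fisher_exact([[a, b], [c, d]])[1])
        records.append({"set": name, "a": a, "b": b, "c": c, "d": d,
                        "odds_ratio": odds, "fisher_p": p})
    return pd.DataFrame(records)
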