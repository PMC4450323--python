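"""Somatic variant calling and longitudinal allele-frequency drift analysis.

The genetic half of the pipeline operates on per-site allele read counts
observed in three samples from one patient: a germline sample and two
pre-treatment leukemia samples (``t1`` near diagnosis, ``t2`` shortly before
treatment).

Somatic sites are identified with a Monte-Carlo permutation test on the
2 x 3 table of (ref, alt) counts across the three samples: under the null
that all three samples share one allele fraction, alt reads are reallocated
among samples with all margins fixed (multivariate hypergeometric) and the
Pearson chi-square statistic is recomputed.  A site is called somatic when
the permutation p-value falls below ``p_threshold`` (default 0.001) *and*
the germline alt-allele fraction is below ``max_germline_af`` (default 0.10).

Allele-frequency drift between the two leukemia time points is tested with a
two-sided 2 x 2 Fisher exact test on deep-amplicon counts, corrected with
Benjamini-Hochberg FDR, and each leukemia is classified from the counts of
significantly rising / falling variants:

* ``evolving``:   >=1 variant up and >=1 down (subclonal selection);
* ``expanding``:  >=2 up and none down (leukemia growing vs normal cells);
* ``static``:     at most one variant changed;
* ``contracting``: >=2 down and none up -- a quadrant the three-category
  scheme leaves uncovered; it gets an explicit label here and can be folded
  into ``static`` with ``fold_contracting=True``.

Copy-number segments are merged into per-patient sCNA groups by
single-linkage on genomic gap (same chromosome, across both time points),
so a region called at both time points counts as one variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SAMPLE_LABELS = ("germline", "t1", "t2")

CATEGORIES = ("evolving", "expanding", "static", "contracting")

#: chromosome loci recurrently altered in CLL, used to label sCNA groups
RECURRENT_LOCI = ("11q", "12", "13q", "17p")


# ---------------------------------------------------------------------------
# somatic calling (2 x 3 permutation chi-square)
# ---------------------------------------------------------------------------

def _chi2_stat(ref: np.ndarray, alt: np.ndarray) -> float:
    """Pearson chi-square statistic of a 2 x k allele-count table."""
    ref = np.asarray(ref, dtype=float)
    alt = np.asarray(alt, dtype=float)
    depth = ref + alt
    n_total = depth.sum()
    n_alt = alt.sum()
    if n_alt == 0 or n_alt == n_total:
        return 0.0
    e_alt = depth * n_alt / n_total
    e_ref = depth * (n_total - n_alt) / n_total
    return float((((alt - e_alt) ** 2) / e_alt + ((ref - e_ref) ** 2) / e_ref).sum())


def chi2_permutation_test(
    ref_counts,
    alt_counts,
    n_perm: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo permutation p-value for a 2 x k allele-count table.

    Under the pooled null, alt reads are redistributed across samples with
    every margin fixed (a multivariate hypergeometric draw) and the Pearson
    chi-square statistic recomputed for each of ``n_perm`` permutations.

    Returns ``p = (1 + #{permuted stat >= observed}) / (1 + n_perm)``, which
    is strictly positive and a valid (slightly conservative) p-value.

    Parameters
    ----------
    ref_counts, alt_counts
        Reference and alternate read counts per sample, ordered
        (germline, t1, t2) for the standard three-sample design.
    n_perm
        Number of permutations (default 10 000).
    seed, rng
        Either a seed or an existing :class:`numpy.random.Generator`;
        the result is deterministic given the seed.
    """
    ref = np.asarray(ref_counts, dtype=np.int64)
    alt = np.asarray(alt_counts, dtype=np.int64)
    if ref.shape != alt.shape or ref.ndim != 1:
        raise ValueError("ref_counts and alt_counts must be 1-D and equal length")
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("read counts must be non-negative")
    depths = ref + alt
    for i, d in enumerate(depths):
        if d == 0:
            label = SAMPLE_LABELS[i] if i < len(SAMPLE_LABELS) else f"sample {i}"
            raise ValueError(f"zero depth in {label} sample")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    n_alt = int(alt.sum())
    n_total = int(depths.sum())
    if n_alt == 0 or n_alt == n_total:
        return 1.0

    observed = _chi2_stat(ref, alt)
    if rng is None:
        rng = np.random.default_rng(seed)
    perm_alt = rng.multivariate_hypergeometric(depths, n_alt, size=n_perm).astype(float)
    d = depths.astype(float)
    e_alt = d * n_alt / n_total
    e_ref = d * (n_total - n_alt) / n_total
    perm_ref = d[None, :] - perm_alt
    perm_stat = (
        ((perm_alt - e_alt) ** 2 / e_alt).sum(axis=1)
        + ((perm_ref - e_ref) ** 2 / e_ref).sum(axis=1)
    )
    # small epsilon keeps exact ties (identical tables) counted as >=
    n_ge = int(np.count_nonzero(perm_stat >= observed - 1e-9))
    return (1 + n_ge) / (1 + n_perm)


@dataclass(frozen=True)
class SomaticCall:
    site_id: str
    p_value: float
    germline_af: float
    is_somatic: bool


def call_somatic(
    site_id: str,
    ref_g: int,
    alt_g: int,
    p_value: float,
    p_threshold: float = 0.001,
    max_germline_af: float = 0.10,
) -> SomaticCall:
    """Apply the somatic thresholds: p < ``p_threshold`` and germline
    alt fraction < ``max_germline_af``."""
    depth_g = ref_g + alt_g
    if depth_g <= 0:
        raise ValueError("germline depth must be positive")
    germline_af = alt_g / depth_g
    is_somatic = bool(p_value < p_threshold and germline_af < max_germline_af)
    return SomaticCall(site_id=site_id, p_value=float(p_value),
                       germline_af=float(germline_af), is_somatic=is_somatic)


def somatic_call_table(
    counts: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    p_threshold: float = 0.001,
    max_germline_af: float = 0.10,
) -> pd.DataFrame:
    """Run the permutation test and somatic thresholds on a count table.

    ``counts`` must carry columns ``site_id, ref_count_g, alt_count_g,
    ref_count_t1, alt_count_t1, ref_count_t2, alt_count_t2``.  Per-site RNG
    streams are spawned from ``seed`` so results do not depend on row order.
    """
    required = ["site_id", "ref_count_g", "alt_count_g", "ref_count_t1",
                "alt_count_t1", "ref_count_t2", "alt_count_t2"]
    missing = [c for c in required if c not in counts.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")

    root = np.random.SeedSequence(seed)
    records = []
    for row, child in zip(counts.itertuples(index=False), root.spawn(len(counts))):
        p = chi2_permutation_test(
            [row.ref_count_g, row.ref_count_t1, row.ref_count_t2],
            [row.alt_count_g, row.alt_count_t1, row.alt_count_t2],
            n_perm=n_perm,
            rng=np.random.default_rng(child),
        )
        call = call_somatic(row.site_id, row.ref_count_g, row.alt_count_g, p,
                            p_threshold=p_threshold,
                            max_germline_af=max_germline_af)
        records.append((call.site_id, call.p_value, call.germline_af, call.is_somatic))
    out = pd.DataFrame(records, columns=["site_id", "p_value", "germline_af", "is_somatic"])
    for col in ("patient_id",):
        if col in counts.columns:
            out.insert(0, col, counts[col].to_numpy())
    return out


# ---------------------------------------------------------------------------
# drift testing (2 x 2 Fisher exact + BH-FDR)
# ---------------------------------------------------------------------------

def fisher_drift_test(ref1: int, alt1: int, ref2: int, alt2: int) -> float:
    """Two-sided Fisher exact p-value for an allele-count change between the
    two leukemia samples (tables with probability <= the observed table's)."""
    for v in (ref1, alt1, ref2, alt2):
        if v < 0:
            raise ValueError("read counts must be non-negative")
    if ref1 + alt1 == 0 or ref2 + alt2 == 0:
        raise ValueError("both samples must have positive depth")
    return float(stats.fisher_exact([[ref1, alt1], [ref2, alt2]],
                                    alternative="two-sided")[1])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, restored to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def drift_test_table(
    counts: pd.DataFrame,
    fdr: float = 0.05,
    per_patient: bool = True,
) -> pd.DataFrame:
    """Per-site drift test across the two leukemia time points.

    Computes allele fractions, two-sided Fisher p, BH q-values (within each
    patient when a ``patient_id`` column is present and ``per_patient``),
    a direction from the allele-fraction point estimates (exact ties get
    ``none`` and count toward neither direction), a significance flag at
    ``q < fdr``, and the absolute allele-fraction change.
    """
    required = ["site_id", "ref_count_t1", "alt_count_t1", "ref_count_t2", "alt_count_t2"]
    missing = [c for c in required if c not in counts.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")

    out = counts.copy().reset_index(drop=True)
    d1 = out["ref_count_t1"] + out["alt_count_t1"]
    d2 = out["ref_count_t2"] + out["alt_count_t2"]
    if (d1 <= 0).any() or (d2 <= 0).any():
        raise ValueError("all sites need positive depth at both time points")
    out["af_t1"] = out["alt_count_t1"] / d1
    out["af_t2"] = out["alt_count_t2"] / d2
    out["fisher_p"] = [
        fisher_drift_test(r.ref_count_t1, r.alt_count_t1, r.ref_count_t2, r.alt_count_t2)
        for r in out.itertuples(index=False)
    ]
    if per_patient and "patient_id" in out.columns:
        out["q_value"] = (
            out.groupby("patient_id", sort=False)["fisher_p"]
            .transform(lambda p: bh_fdr(p.to_numpy()))
        )
    else:
        out["q_value"] = bh_fdr(out["fisher_p"].to_numpy())
    out["direction"] = np.select(
        [out["af_t2"] > out["af_t1"], out["af_t2"] < out["af_t1"]],
        ["up", "down"], default="none",
    )
    out["significant"] = out["q_value"] < fdr
    out["abs_change"] = (out["af_t2"] - out["af_t1"]).abs()
    keep = [c for c in ("patient_id", "site_id", "af_t1", "af_t2", "fisher_p",
                        "q_value", "direction", "significant", "abs_change")
            if c in out.columns]
    return out[keep]


# ---------------------------------------------------------------------------
# evolution-pattern classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvolutionCall:
    patient_id: str
    n_up: int
    n_down: int
    n_tested: int
    category: str
    median_abs_change_significant: float
    frac_changed: float


def classify_evolution(
    drift: pd.DataFrame,
    patient_id: str = "",
    fold_contracting: bool = False,
) -> EvolutionCall:
    """Classify one patient's leukemia from its drift-test results.

    ``drift`` is one patient's slice of :func:`drift_test_table` output.
    Significant sites with direction ``none`` (exact allele-fraction ties)
    count toward neither ``n_up`` nor ``n_down``.
    """
    if len(drift) == 0:
        warnings.warn(f"no drift results for patient {patient_id!r}; "
                      "classified static with n_tested=0", stacklevel=2)
        return EvolutionCall(patient_id, 0, 0, 0, "static", float("nan"), 0.0)

    sig = drift[drift["significant"]]
    n_up = int((sig["direction"] == "up").sum())
    n_down = int((sig["direction"] == "down").sum())
    n_tested = int(len(drift))

    if n_up >= 1 and n_down >= 1:
        category = "evolving"
    elif n_up >= 2 and n_down == 0:
        category = "expanding"
    elif n_down >= 2 and n_up == 0:
        category = "static" if fold_contracting else "contracting"
    else:  # n_up + n_down <= 1
        category = "static"

    med = float(sig["abs_change"].median()) if len(sig) else float("nan")
    frac = (n_up + n_down) / n_tested
    pid = patient_id or (str(drift["patient_id"].iloc[0]) if "patient_id" in drift else "")
    return EvolutionCall(pid, n_up, n_down, n_tested, category, med, frac)


def classify_cohort(drift: pd.DataFrame, fold_contracting: bool = False) -> pd.DataFrame:
    """Apply :func:`classify_evolution` per patient; returns one row each."""
    if "patient_id" not in drift.columns:
        raise ValueError("cohort drift table needs a patient_id column")
    calls = [
        classify_evolution(grp, patient_id=str(pid), fold_contracting=fold_contracting)
        for pid, grp in drift.groupby("patient_id", sort=True)
    ]
    return pd.DataFrame([c.__dict__ for c in calls])


# ---------------------------------------------------------------------------
# sCNA grouping
# ---------------------------------------------------------------------------

def load_recurrent_loci() -> pd.DataFrame:
    """Bundled hg19 coordinates of the four recurrently altered CLL loci
    (11q, trisomy 12, 13q, 17p).  Configuration data, not code."""
    path = resources.files("progressionkit").joinpath("data/cll_loci.tsv")
    with resources.as_file(path) as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def group_cna_segments(segments: pd.DataFrame, merge_distance: int = 1_000_000) -> pd.DataFrame:
    """Merge CNV segment calls into per-patient sCNA groups.

    Single-linkage: same-chromosome segments (from either time point, for
    the same patient) whose genomic gap is <= ``merge_distance`` join one
    group.  Coordinates are 0-based half-open.  Returns one row per group
    with the merged span, member count and time-point presence
    (``both`` / ``first_only`` / ``second_only``).
    """
    required = ["chrom", "start", "end", "timepoint"]
    missing = [c for c in required if c not in segments.columns]
    if missing:
        raise ValueError(f"segment table missing columns: {missing}")
    if (segments["end"] <= segments["start"]).any():
        raise ValueError("segments must satisfy end > start")

    has_patient = "patient_id" in segments.columns
    keys = ["patient_id", "chrom"] if has_patient else ["chrom"]
    groups = []
    for key, grp in segments.groupby(keys, sort=True):
        grp = grp.sort_values(["start", "end"], kind="mergesort")
        cur: list[pd.Series] = []
        cur_end = None
        for _, seg in grp.iterrows():
            if cur and seg["start"] - cur_end > merge_distance:
                groups.append(cur)
                cur = []
            cur.append(seg)
            cur_end = max(cur_end, seg["end"]) if cur_end is not None and len(cur) > 1 else seg["end"]
        if cur:
            groups.append(cur)

    records = []
    for i, members in enumerate(groups):
        tps = {str(m["timepoint"]) for m in members}
        if tps >= {"t1", "t2"}:
            presence = "both"
        elif tps == {"t1"}:
            presence = "first_only"
        else:
            presence = "second_only"
        rec = {
            "group_id": f"g{i}",
            "chrom": str(members[0]["chrom"]),
            "start": int(min(m["start"] for m in members)),
            "end": int(max(m["end"] for m in members)),
            "n_segments": len(members),
            "presence": presence,
        }
        if has_patient:
            rec["patient_id"] = members[0]["patient_id"]
        records.append(rec)
    cols = (["patient_id"] if has_patient else []) + [
        "group_id", "chrom", "start", "end", "n_segments", "presence"]
    return pd.DataFrame(records, columns=cols)


def assign_locus_labels(groups: pd.DataFrame, loci: pd.DataFrame | None = None) -> pd.Series:
    """Label each sCNA group with the recurrent CLL locus it overlaps
    (11q / 12 / 13q / 17p) or ``other``."""
    if loci is None:
        loci = load_recurrent_loci()
    labels = []
    for _, g in groups.iterrows():
        label = "other"
        for _, loc in loci.iterrows():
            if (str(g["chrom"]) == str(loc["chrom"])
                    and g["start"] < loc["end"] and loc["start"] < g["end"]):
                label = str(loc["label"])
                break
        labels.append(label)
    return pd.Series(labels, index=groups.index, name="locus_label")
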