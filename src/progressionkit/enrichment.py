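"""CpG annotation against ChIP-seq peaks and gene-set enrichment.

Significant CpGs are intersected with ChIP-seq peak intervals through a
window centered on the probe base (default 200 bp, i.e. "within 100 bp of a
peak"), with enrichment assessed by an upper-tail hypergeometric test.
Gene-set association corrects the well-known probe-representation bias of
methylation arrays (genes with more probes are more likely to contain a
significant CpG by chance) with a weighted-resampling null in which genes
enter the null hit set with probability proportional to their probe count.
Fixed published CpG/gene lists are compared with a 2x2 Fisher exact test
over an explicit universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats


# ---------------------------------------------------------------------------
# window / peak overlap
# ---------------------------------------------------------------------------

def window_peak_overlap(
    cpgs: pd.DataFrame,
    peaks: pd.DataFrame,
    window: int = 200,
) -> pd.Series:
    """Flag CpGs whose probe base lies within ``window/2`` bp of a peak.

    ``cpgs`` needs columns ``cpg_id, chrom, pos`` (1-based probe coordinate);
    ``peaks`` needs ``chrom, start, end`` (0-based half-open, BED-style).
    A probe at 1-based position p is flagged iff the 0-based interval
    [p-1-window/2, p-1+window/2+1) intersects at least one peak, so a peak
    starting exactly window/2 bp downstream still counts and one base
    further does not.  Probes on chromosomes absent from the peak set are
    warned about and flagged False.
    """
    if window <= 0 or window % 2:
        raise ValueError("window must be a positive even integer")
    if (peaks["end"] <= peaks["start"]).any():
        raise ValueError("peaks must satisfy end > start")
    half = window // 2

    trees: dict[str, IntervalTree] = {}
    for chrom, grp in peaks.groupby("chrom", sort=False):
        trees[str(chrom)] = IntervalTree.from_tuples(
            zip(grp["start"].astype(int), grp["end"].astype(int)))

    unknown = sorted(set(cpgs["chrom"].astype(str)) - set(trees))
    if unknown:
        warnings.warn(f"no peaks on chromosomes {unknown}; probes there "
                      "treated as non-overlapping", stacklevel=2)

    flags = []
    for chrom, pos in zip(cpgs["chrom"].astype(str), cpgs["pos"].astype(int)):
        tree = trees.get(chrom)
        if tree is None:
            flags.append(False)
            continue
        p0 = pos - 1
        flags.append(bool(tree.overlaps(p0 - half, p0 + half + 1)))
    return pd.Series(flags, index=pd.Index(cpgs["cpg_id"], name="cpg_id"),
                     name="peak_overlap")


def hypergeometric_enrichment(
    n_universe: int,
    n_flagged_universe: int,
    n_selected: int,
    n_flagged_selected: int,
) -> float:
    """Upper-tail hypergeometric enrichment p-value, P(X >= x) with
    X ~ Hypergeom(N=n_universe, K=n_flagged_universe, n=n_selected)."""
    N, K, n, x = n_universe, n_flagged_universe, n_selected, n_flagged_selected
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("inconsistent universe counts")
    if not (0 <= x <= min(n, K)):
        raise ValueError("n_flagged_selected exceeds its margins")
    return float(stats.hypergeom.sf(x - 1, N, K, n))


# ---------------------------------------------------------------------------
# probe-bias-corrected gene-set association
# ---------------------------------------------------------------------------

def _gene_probe_counts(annotation: pd.DataFrame, cpg_ids: set[str]) -> pd.Series:
    """Number of probes per gene, restricted to the given CpG universe.

    ``annotation`` has columns ``cpg_id`` and ``gene_symbols`` (list or
    semicolon-joined string; empty means intergenic).
    """
    counts: dict[str, int] = {}
    sub = annotation[annotation["cpg_id"].isin(cpg_ids)]
    for genes in sub["gene_symbols"]:
        for g in _split_genes(genes):
            counts[g] = counts.get(g, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def _split_genes(genes) -> list[str]:
    if isinstance(genes, str):
        return [g for g in genes.split(";") if g]
    if genes is None or (isinstance(genes, float) and np.isnan(genes)):
        return []
    return [str(g) for g in genes]


def probe_bias_geneset_test(
    sig_cpgs: Iterable[str],
    all_cpgs: Iterable[str],
    annotation: pd.DataFrame,
    gene_sets: Mapping[str, Iterable[str]],
    n_resamples: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-set enrichment of significant CpGs, corrected for probe bias.

    A gene is a "hit" when at least one of its probes is significant.  The
    null distribution of per-set hit counts is built by drawing, for each of
    ``n_resamples`` resamples, the observed number of hit genes *without*
    replacement with probability proportional to each gene's probe count
    (Efraimidis-Spirakis Gumbel top-k sampling), so probe-rich genes enter
    the null as often as the array design favors them.  Per-set
    ``p = (1 + #{null >= observed}) / (1 + n_resamples)``.
    """
    sig_cpgs = set(sig_cpgs)
    all_cpgs = set(all_cpgs)
    if not sig_cpgs <= all_cpgs:
        raise ValueError("significant CpGs must be a subset of the universe")
    probe_counts = _gene_probe_counts(annotation, all_cpgs)
    if probe_counts.empty:
        raise ValueError("no annotated genes in the CpG universe")
    genes = probe_counts.index.to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}

    hit_counts = _gene_probe_counts(annotation, sig_cpgs)
    hit_mask = np.zeros(len(genes), dtype=bool)
    for g in hit_counts.index:
        hit_mask[gene_pos[g]] = True
    n_hits = int(hit_mask.sum())

    rng = np.random.default_rng(seed)
    log_w = np.log(probe_counts.to_numpy(float))
    # Gumbel top-k draw per resample = weighted sampling without replacement
    null_members = np.empty((n_resamples, n_hits), dtype=np.int64)
    chunk = max(1, int(2e7 // max(len(genes), 1)))
    for start in range(0, n_resamples, chunk):
        stop = min(start + chunk, n_resamples)
        keys = log_w[None, :] + rng.gumbel(size=(stop - start, len(genes)))
        null_members[start:stop] = np.argpartition(-keys, n_hits - 1, axis=1)[:, :n_hits]

    records = []
    for name, members in gene_sets.items():
        member_mask = np.zeros(len(genes), dtype=bool)
        annotated = [g for g in set(members) if g in gene_pos]
        if not annotated:
            warnings.warn(f"gene set {name!r} has no annotated genes; skipped",
                          stacklevel=2)
            continue
        member_mask[[gene_pos[g] for g in annotated]] = True
        observed = int((hit_mask & member_mask).sum())
        null_counts = member_mask[null_members].sum(axis=1)
        p = (1 + int((null_counts >= observed).sum())) / (1 + n_resamples)
        records.append({
            "gene_set": name,
            "n_genes_annotated": len(annotated),
            "n_hit_genes": observed,
            "null_mean": float(null_counts.mean()),
            "p_value": p,
        })
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# published-list overlap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapResult:
    n_overlap: int
    fisher_p: float
    table: tuple[tuple[int, int], tuple[int, int]]


def list_overlap_test(
    selected: Iterable[str],
    published: Iterable[str],
    universe: Iterable[str],
    restrict_to: Iterable[str] | None = None,
) -> OverlapResult:
    """Fisher exact overlap between a selected set and a published list.

    Membership is tabulated over ``universe``; when ``restrict_to`` is given
    (e.g. probes shared with an older array platform) the universe and both
    lists are intersected with it first.  A published list disjoint from the
    universe raises (wrong universe supplied).
    """
    universe = set(universe)
    if restrict_to is not None:
        universe &= set(restrict_to)
    published = set(published) & universe
    if not published:
        raise ValueError("published list is disjoint from the universe")
    selected = set(selected) & universe
    a = len(selected & published)
    b = len(selected - published)
    c = len(published - selected)
    d = len(universe) - a - b - c
    p = float(stats.fisher_exact([[a, b], [c, d]])[1])
    return OverlapResult(n_overlap=a, fisher_p=p, table=((a, b), (c, d)))
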