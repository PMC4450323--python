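"""Comparison of progression CpGs with naive / memory B-cell methylomes.

Progression-associated CpGs are interpreted against normal B-cell
development: per-CpG differences of group means between naive B cells,
memory B cells and the first CLL time point, with a +/-10% (0.10 beta)
difference call; hypergeometric enrichment of progression CpGs among the
differing sites; direction-of-change concordance; and average-linkage
hierarchical clustering of samples restricted to the progression CpGs,
with each leukemia sample assigned to its nearest reference group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import cdist, pdist
from skbio.tree import TreeNode

from .enrichment import hypergeometric_enrichment

PAIRS = ("naive_memory", "naive_cll1", "memory_cll1")


def groupwise_deltas(
    naive: pd.DataFrame,
    memory: pd.DataFrame,
    cll_t1: pd.DataFrame,
    threshold: float = 0.10,
) -> pd.DataFrame:
    """Per-CpG deltas of group means for the three pairwise comparisons.

    Deltas are oriented second-group minus first: ``naive_memory`` =
    mean(memory) - mean(naive), etc.  ``diff_<pair>`` flags |delta| >=
    ``threshold`` (default 0.10, the "at least +/-10%" rule).
    """
    for name, df in (("naive", naive), ("memory", memory), ("cll_t1", cll_t1)):
        if df.shape[1] == 0:
            raise ValueError(f"{name} group has no samples")
    idx = naive.index.intersection(memory.index).intersection(cll_t1.index)
    if len(idx) == 0:
        raise ValueError("no shared CpGs across the three groups")
    m_naive = naive.loc[idx].mean(axis=1)
    m_memory = memory.loc[idx].mean(axis=1)
    m_cll = cll_t1.loc[idx].mean(axis=1)
    out = pd.DataFrame({
        "mean_naive": m_naive,
        "mean_memory": m_memory,
        "mean_cll1": m_cll,
        "delta_naive_memory": m_memory - m_naive,
        "delta_naive_cll1": m_cll - m_naive,
        "delta_memory_cll1": m_cll - m_memory,
    })
    for pair in PAIRS:
        out[f"diff_{pair}"] = out[f"delta_{pair}"].abs() >= threshold
    out.index.name = "cpg_id"
    return out


def overlap_enrichment_three_way(
    comparison: pd.DataFrame,
    progression_cpgs: Iterable[str],
    h3k27me3_cpgs: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of progression CpGs among differing sites.

    For each pairwise comparison, tests whether progression-associated CpGs
    (and, when given, their H3K27me3-flagged stratum) are over-represented
    among the CpGs that differ by >= the threshold, against the universe of
    all CpGs in ``comparison``.  Empty differing sets yield p = 1.
    """
    universe = set(comparison.index)
    strata = {"all_progression": set(progression_cpgs) & universe}
    if h3k27me3_cpgs is not None:
        strata["h3k27me3_progression"] = strata["all_progression"] & set(h3k27me3_cpgs)
    records = []
    for pair in PAIRS:
        differing = set(comparison.index[comparison[f"diff_{pair}"]])
        for stratum_name, stratum in strata.items():
            if not differing:
                warnings.warn(f"no differing CpGs for {pair}; p=1", stacklevel=2)
                p = 1.0
                x = 0
            else:
                x = len(stratum & differing)
                p = hypergeometric_enrichment(len(universe), len(differing),
                                              len(stratum), x)
            records.append({"pair": pair, "stratum": stratum_name,
                            "n_differing": len(differing),
                            "n_stratum": len(stratum),
                            "n_overlap": x, "p_value": p})
    return pd.DataFrame(records)


@dataclass(frozen=True)
class ConcordanceSummary:
    pair: str
    stratum: str
    n_overlap: int
    pct_same_direction: float


def direction_concordance(
    progression_deltas: pd.Series,
    comparison: pd.DataFrame,
    pair: str,
    stratum: Iterable[str] | None = None,
    stratum_name: str = "all",
) -> ConcordanceSummary:
    """Percent of CpGs changing in the same direction during progression as
    between two B-cell states.

    Considers CpGs that are in the progression set (``progression_deltas``
    index), differ by >= the threshold for ``pair``, and fall in ``stratum``
    when given.  Zero deltas on either side carry no direction and are
    excluded.  An empty overlap is reported with NaN percent.
    """
    if pair not in PAIRS:
        raise ValueError(f"pair must be one of {PAIRS}")
    cpgs = set(progression_deltas.index) & set(
        comparison.index[comparison[f"diff_{pair}"]])
    if stratum is not None:
        cpgs &= set(stratum)
    cpgs = sorted(cpgs)
    if not cpgs:
        warnings.warn(f"empty overlap for {pair}/{stratum_name}; "
                      "concordance undefined", stacklevel=2)
        return ConcordanceSummary(pair, stratum_name, 0, float("nan"))
    prog = progression_deltas.loc[cpgs]
    comp = comparison.loc[cpgs, f"delta_{pair}"]
    nonzero = (prog != 0) & (comp != 0)
    prog, comp = prog[nonzero], comp[nonzero]
    if len(prog) == 0:
        return ConcordanceSummary(pair, stratum_name, 0, float("nan"))
    same = np.sign(prog.to_numpy()) == np.sign(comp.to_numpy())
    return ConcordanceSummary(pair, stratum_name, int(len(prog)),
                              float(100.0 * same.mean()))


def similarity_clustering(
    samples: pd.DataFrame,
    reference_groups: pd.Series,
    cpgs: Iterable[str] | None = None,
) -> tuple[str, pd.DataFrame]:
    """Cluster samples at the progression CpGs and call nearest reference.

    ``samples`` is CpG x sample (leukemia and reference columns together);
    ``reference_groups`` maps reference sample ids to ``naive``/``memory``
    (samples absent from it are the query leukemias).  Restricting to
    ``cpgs`` first when given, performs average-linkage hierarchical
    clustering on Euclidean distances and, per query sample, reports the
    reference group with the smaller mean distance.

    Returns the dendrogram as a Newick string plus a per-query table with
    mean distances and the nearest-reference call.  A constant matrix
    (all distances zero) is flagged degenerate.
    """
    if samples.shape[1] < 2:
        raise ValueError("clustering needs at least two samples")
    mat = samples.loc[list(cpgs)] if cpgs is not None else samples
    X = mat.to_numpy(float).T  # samples x cpgs

    dists = pdist(X, metric="euclidean")
    degenerate = bool(np.allclose(dists, 0.0))
    if degenerate:
        warnings.warn("all pairwise distances are zero; dendrogram is "
                      "degenerate", stacklevel=2)
    Z = linkage(X, method="average", metric="euclidean")
    tree = TreeNode.from_linkage_matrix(Z, id_list=list(mat.columns))
    newick = str(tree)

    naive_cols = [s for s, g in reference_groups.items() if g == "naive"]
    memory_cols = [s for s, g in reference_groups.items() if g == "memory"]
    if not naive_cols or not memory_cols:
        raise ValueError("reference_groups must name naive and memory samples")
    queries = [s for s in mat.columns if s not in set(reference_groups.index)]
    records = []
    for s in queries:
        v = mat[s].to_numpy(float)[None, :]
        d_naive = float(cdist(v, mat[naive_cols].to_numpy(float).T).mean())
        d_memory = float(cdist(v, mat[memory_cols].to_numpy(float).T).mean())
        records.append({"sample_id": s, "mean_dist_naive": d_naive,
                        "mean_dist_memory": d_memory,
                        "nearest": "memory" if d_memory < d_naive else "naive",
                        "degenerate": degenerate})
    return newick, pd.DataFrame(records)
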