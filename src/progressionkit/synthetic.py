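"""Synthetic cohort generation with known ground truth.

Emulates the data regimes of a two-time-point, pre-treatment CLL cohort:

* **Genetic**: per-patient subclone structures (2-9 clones, truncal and
  subclonal variants), heterozygous diploid variants whose expected alt
  fraction at time t is ``purity_t * prevalence_t / 2``, read counts drawn
  binomially at Poisson depths (exome ~75-150x for discovery, amplicon
  ~850x for validation/drift), plus germline het / hom sites.  Patients are
  planted as evolving (one subclone gains ~0.25 prevalence from another),
  expanding (purity rises ~0.15, all variants drift up) or static
  (identical clone fractions and purity).

* **Methylation**: 5-cell-type beta mixtures (B-dominant, with the B
  fraction drifting up at the second time point, mimicking rising tumor
  load), a reference marker panel, and planted progression effects at the
  second time point only: ~77% methylation gains, effects 0.005-0.095 with
  median ~0.029, concentrated under an H3K27me3 flag at a configurable
  odds ratio.  Truncated Gaussian noise; all betas clamped to [0, 1].

* **B-cell development references**: naive and memory profiles whose
  differences at progression CpGs are direction-consistent with the
  planted progression deltas.

Every generator takes a :class:`numpy.random.Generator` (or a seed via
``SimulationConfig.seed``) and is bit-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .methylation import CELL_TYPES, BetaMatrix, ReferencePanel

GENETIC_CATEGORIES = ("evolving", "expanding", "static")


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults mirror the emulated study.

    Genetic: 26-80 coding variants per patient, 2-9 subclones, exome depth
    ~120x (within the 75-150x band), amplicon depth ~850x, category mix
    (0.26, 0.26, 0.48) for evolving/expanding/static.  Methylation: planted
    effects on the beta scale with median 0.029 in [0.005, 0.095], 77%
    increases, noise sd 0.02.
    """

    # cohort
    n_patients: int = 27
    seed: int = 0
    # genetic
    depth_exome: float = 120.0
    depth_amplicon: float = 850.0
    n_variants_min: int = 26
    n_variants_max: int = 80
    n_clones_min: int = 2
    n_clones_max: int = 9
    truncal_fraction: float = 0.5
    purity_min: float = 0.70
    purity_max: float = 0.80
    purity_shift: float = 0.15
    prevalence_shift: float = 0.25
    category_probs: tuple[float, float, float] = (0.26, 0.26, 0.48)
    n_germline_het: int = 20
    n_germline_hom_alt: int = 5
    n_germline_hom_ref: int = 5
    # methylation
    n_cpgs: int = 20_000
    n_markers_per_type: int = 50
    frac_progression_cpgs: float = 0.01
    effect_median: float = 0.029
    effect_min: float = 0.005
    effect_max: float = 0.095
    frac_increase: float = 0.77
    noise_sd: float = 0.02
    h3k27_background: float = 0.20
    h3k27_odds_ratio: float = 3.0
    b_fraction_min: float = 0.75
    b_fraction_max: float = 0.90
    b_fraction_gain_max: float = 0.08

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.depth_exome <= 0 or self.depth_amplicon <= 0:
            raise ValueError("sequencing depths must be positive")
        if self.n_clones_min < 1 or self.n_clones_max < self.n_clones_min:
            raise ValueError("invalid clone-count range")
        if not (0 <= self.truncal_fraction <= 1):
            raise ValueError("truncal_fraction must lie in [0, 1]")
        if not (0 < self.purity_min <= self.purity_max <= 1):
            raise ValueError("purity bounds must satisfy 0 < min <= max <= 1")
        if abs(sum(self.category_probs) - 1.0) > 1e-9 or min(self.category_probs) < 0:
            raise ValueError("category_probs must be non-negative and sum to 1")
        if not (0 <= self.effect_min <= self.effect_median <= self.effect_max <= 1):
            raise ValueError("need effect_min <= effect_median <= effect_max in [0, 1]")
        for name in ("frac_progression_cpgs", "frac_increase", "h3k27_background"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class CloneStructure:
    """One patient's subclone layout across the two time points."""

    patient_id: str
    clone_fractions_t1: np.ndarray
    clone_fractions_t2: np.ndarray
    variant_assignments: dict[str, int | None]  # None = truncal
    purity_t1: float
    purity_t2: float
    category: str

    def __post_init__(self) -> None:
        for name in ("clone_fractions_t1", "clone_fractions_t2"):
            f = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, f)
            if (f < -1e-12).any() or f.sum() > 1 + 1e-9:
                raise ValueError(f"{name}: clone fractions must be >= 0 and sum to <= 1")
        if self.clone_fractions_t1.shape != self.clone_fractions_t2.shape:
            raise ValueError("clone fraction vectors must match in length")
        if len(self.clone_fractions_t1) == 0:
            raise ValueError("empty clone set")

    def expected_vaf(self, variant: str, timepoint: str) -> float:
        """Expected alt fraction: purity * prevalence / 2 (het, diploid)."""
        fractions = {"t1": self.clone_fractions_t1, "t2": self.clone_fractions_t2}[timepoint]
        purity = {"t1": self.purity_t1, "t2": self.purity_t2}[timepoint]
        clone = self.variant_assignments[variant]
        prevalence = 1.0 if clone is None else float(fractions[clone])
        return purity * prevalence / 2.0


@dataclass
class GroundTruth:
    """What the simulator actually planted, for downstream scoring."""

    true_somatic_sites: set[str] = field(default_factory=set)
    true_drift_directions: dict[str, str] = field(default_factory=dict)
    true_category: dict[str, str] = field(default_factory=dict)
    true_compositions: pd.DataFrame | None = None
    true_progression_cpgs: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# genetic cohort
# ---------------------------------------------------------------------------

def make_clone_structure(
    patient_id: str,
    category: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_variants: int | None = None,
) -> CloneStructure:
    """Build one patient's subclone structure for a planted category."""
    if category not in GENETIC_CATEGORIES:
        raise ValueError(f"category must be one of {GENETIC_CATEGORIES}")
    n_clones = int(rng.integers(config.n_clones_min, config.n_clones_max + 1))
    purity_t1 = float(rng.uniform(config.purity_min, config.purity_max))
    purity_t2 = purity_t1
    shift = config.prevalence_shift

    if category == "evolving":
        n_clones = max(n_clones, 2)
        f_up = float(rng.uniform(0.05, 0.15))
        f_down = shift + float(rng.uniform(0.02, 0.10))
        rest_total = (1.0 - f_up - f_down - shift) * float(rng.uniform(0.4, 0.8))
        others = rng.dirichlet(np.ones(n_clones - 2)) * rest_total if n_clones > 2 else np.array([])
        t1 = np.concatenate([[f_up, f_down], others])
        t2 = t1.copy()
        t2[0] += shift
        t2[1] -= shift
    else:
        t1 = rng.dirichlet(np.ones(n_clones)) * float(rng.uniform(0.5, 0.9))
        t2 = t1.copy()
        if category == "expanding":
            purity_t2 = min(purity_t1 + config.purity_shift, 0.98)

    if n_variants is None:
        n_variants = int(rng.integers(config.n_variants_min, config.n_variants_max + 1))
    assignments: dict[str, int | None] = {}
    for i in range(n_variants):
        vid = f"{patient_id}_v{i:03d}"
        if rng.random() < config.truncal_fraction:
            assignments[vid] = None
        else:
            assignments[vid] = int(rng.integers(0, n_clones))
    return CloneStructure(patient_id, t1, t2, assignments, purity_t1, purity_t2, category)


def _binomial_counts(rng: np.random.Generator, vaf: np.ndarray, mean_depth: float):
    depth = np.maximum(rng.poisson(mean_depth, size=vaf.shape), 1)
    alt = rng.binomial(depth, np.clip(vaf, 0.0, 1.0))
    return depth - alt, alt


@dataclass
class GeneticCohort:
    exome_counts: pd.DataFrame
    amplicon_counts: pd.DataFrame
    clone_structures: dict[str, CloneStructure]
    truth: GroundTruth


def simulate_genetic_cohort(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    categories: Mapping[str, str] | None = None,
) -> GeneticCohort:
    """Simulate tri-sample allele counts for a cohort with planted dynamics.

    Returns exome-depth and amplicon-depth count tables (one row per site,
    columns ``patient_id, site_id, chrom, pos, ref_count_g, alt_count_g,
    ref_count_t1, alt_count_t1, ref_count_t2, alt_count_t2``) together with
    clone structures and ground truth.  ``categories`` optionally pins each
    patient's planted category; otherwise categories are drawn from
    ``config.category_probs``.
    """
    config.validate()
    if rng is None:
        rng = config.rng()

    truth = GroundTruth()
    structures: dict[str, CloneStructure] = {}
    exome_rows, amplicon_rows = [], []
    for p in range(config.n_patients):
        pid = f"P{p:03d}"
        if categories is not None:
            category = categories[pid]
        else:
            category = str(rng.choice(GENETIC_CATEGORIES, p=config.category_probs))
        cs = make_clone_structure(pid, category, config, rng)
        structures[pid] = cs
        truth.true_category[pid] = category

        site_records = []
        pos = 1000
        for vid in cs.variant_assignments:
            v1 = cs.expected_vaf(vid, "t1")
            v2 = cs.expected_vaf(vid, "t2")
            site_records.append((vid, 0.0, v1, v2, True))
            truth.true_somatic_sites.add(vid)
            if v2 > v1 + 1e-12:
                truth.true_drift_directions[vid] = "up"
            elif v2 < v1 - 1e-12:
                truth.true_drift_directions[vid] = "down"
            else:
                truth.true_drift_directions[vid] = "none"
        germline_blocks = (
            (config.n_germline_het, 0.5, "het"),
            (config.n_germline_hom_alt, 1.0, "hom"),
            (config.n_germline_hom_ref, 0.0, "ref"),
        )
        for n_sites, af, tag in germline_blocks:
            for i in range(n_sites):
                site_records.append((f"{pid}_g{tag}{i:02d}", af, af, af, False))

        vaf_g = np.array([r[1] for r in site_records])
        vaf_1 = np.array([r[2] for r in site_records])
        vaf_2 = np.array([r[3] for r in site_records])
        for depth, rows in ((config.depth_exome, exome_rows),
                            (config.depth_amplicon, amplicon_rows)):
            rg, ag = _binomial_counts(rng, vaf_g, depth)
            r1, a1 = _binomial_counts(rng, vaf_1, depth)
            r2, a2 = _binomial_counts(rng, vaf_2, depth)
            for j, (sid, *_rest) in enumerate(site_records):
                rows.append((pid, sid, "1", pos + j * 1000,
                             rg[j], ag[j], r1[j], a1[j], r2[j], a2[j]))

    cols = ["patient_id", "site_id", "chrom", "pos", "ref_count_g", "alt_count_g",
            "ref_count_t1", "alt_count_t1", "ref_count_t2", "alt_count_t2"]
    return GeneticCohort(
        exome_counts=pd.DataFrame(exome_rows, columns=cols),
        amplicon_counts=pd.DataFrame(amplicon_rows, columns=cols),
        clone_structures=structures,
        truth=truth,
    )


def simulate_cna_segments(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    frac_with_recurrent: float = 13 / 19,
) -> pd.DataFrame:
    """Synthetic CNV segment calls touching the recurrent CLL loci.

    Each patient carries, with probability ``frac_with_recurrent``, one
    deletion/trisomy at a recurrent locus (segmented into 1-3 jittered
    pieces per time point, usually present at both).
    """
    from .somatic import load_recurrent_loci

    config.validate()
    if rng is None:
        rng = config.rng()
    loci = load_recurrent_loci()
    rows = []
    for p in range(config.n_patients):
        pid = f"P{p:03d}"
        if rng.random() >= frac_with_recurrent:
            continue
        locus = loci.iloc[int(rng.integers(0, len(loci)))]
        span = int(locus["end"] - locus["start"])
        start = int(locus["start"] + rng.integers(0, max(span // 4, 1)))
        length = int(rng.integers(2_000_000, 10_000_000))
        end = min(start + length, int(locus["end"]))
        cn = 3 if locus["label"] == "12" else 1
        timepoints = ("t1", "t2") if rng.random() < 0.85 else ("t2",)
        for tp in timepoints:
            n_pieces = int(rng.integers(1, 4))
            cuts = np.sort(rng.integers(start + 1, end, size=n_pieces - 1)) if n_pieces > 1 else []
            bounds = [start, *cuts, end]
            for a, b in zip(bounds[:-1], bounds[1:]):
                rows.append((pid, str(locus["chrom"]), int(a), int(b), cn,
                             float(rng.uniform(40, 90)), tp))
    return pd.DataFrame(rows, columns=["patient_id", "chrom", "start", "end",
                                       "copy_number", "confidence", "timepoint"])


# ---------------------------------------------------------------------------
# methylation cohort
# ---------------------------------------------------------------------------

def _effect_beta_b(config: SimulationConfig, a: float = 2.0) -> float:
    """Second Beta shape parameter so the scaled effect median matches
    ``effect_median`` (Beta median approximation (a-1/3)/(a+b-2/3))."""
    span = config.effect_max - config.effect_min
    if span <= 0:
        return a
    m = (config.effect_median - config.effect_min) / span
    m = min(max(m, 0.05), 0.95)
    return max((a - 1 / 3) / m - a + 2 / 3, 0.1)


@dataclass
class ReferenceProfiles:
    """Full per-cell-type beta profiles plus the marker subset."""

    profiles: pd.DataFrame  # all CpGs x cell types
    marker_ids: pd.Index

    @property
    def panel(self) -> ReferencePanel:
        return ReferencePanel(self.profiles.loc[self.marker_ids])


def make_reference_profiles(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ReferenceProfiles:
    """Cell-type beta profiles over all CpGs, with cell-type-specific
    marker blocks (first ``5 * n_markers_per_type`` CpGs)."""
    config.validate()
    if rng is None:
        rng = config.rng()
    n = config.n_cpgs
    cpg_ids = pd.Index([f"cg{i:08d}" for i in range(n)], name="cpg_id")
    base = rng.beta(0.4, 0.4, size=n)
    profiles = {}
    for ct in CELL_TYPES:
        # between-cell-type divergence: genome-wide profiles correlate highly
        # but differ by a few percent beta at typical CpGs
        profiles[ct] = np.clip(base + rng.normal(0.0, 0.05, size=n), 0.02, 0.98)
    prof = pd.DataFrame(profiles, index=cpg_ids)

    n_mark = config.n_markers_per_type
    if 5 * n_mark > n:
        raise ValueError("n_cpgs too small for the requested marker count")
    markers = []
    for t_idx, ct in enumerate(CELL_TYPES):
        block = slice(t_idx * n_mark, (t_idx + 1) * n_mark)
        ids = cpg_ids[block]
        markers.extend(ids)
        for j, cid in enumerate(ids):
            hyper = j % 2 == 0
            prof.loc[cid, :] = 0.10 if hyper else 0.90
            prof.loc[cid, ct] = 0.90 if hyper else 0.10
    return ReferenceProfiles(profiles=prof, marker_ids=pd.Index(markers))


@dataclass
class MethylationCohort:
    betas: BetaMatrix
    reference: ReferenceProfiles
    annotation: pd.DataFrame  # cpg_id, chrom, pos, gene_symbols, h3k27me3_flag
    peaks: pd.DataFrame       # chrom, start, end (synthetic H3K27me3 peaks)
    truth: GroundTruth


def simulate_methylation_cohort(
    config: SimulationConfig,
    reference: ReferenceProfiles | None = None,
    rng: np.random.Generator | None = None,
) -> MethylationCohort:
    """Simulate a paired methylation cohort with planted progression CpGs.

    Each sample's beta vector is (reference profiles x composition), plus at
    the second time point the planted signed progression deltas, plus
    truncated Gaussian noise; betas are clamped to [0, 1].  The B-cell
    fraction drifts upward at t2, creating the composition confounding the
    adjustment step must remove.  H3K27me3 flags are drawn so planted CpGs
    are enriched under the flag at ``config.h3k27_odds_ratio``.
    """
    config.validate()
    if rng is None:
        rng = config.rng()
    if reference is None:
        reference = make_reference_profiles(config, rng=rng)
    prof = reference.profiles
    n = len(prof)
    cpg_ids = prof.index

    # planted progression CpGs (never at marker CpGs)
    eligible = cpg_ids.difference(reference.marker_ids)
    n_planted = int(round(config.frac_progression_cpgs * n))
    planted = pd.Index(rng.choice(eligible.to_numpy(), size=n_planted, replace=False))
    up = rng.random(n_planted) < config.frac_increase
    b_shape = _effect_beta_b(config)
    effects = config.effect_min + (config.effect_max - config.effect_min) * \
        rng.beta(2.0, b_shape, size=n_planted)
    signed = np.where(up, effects, -effects)
    delta = pd.Series(0.0, index=cpg_ids)
    delta.loc[planted] = signed

    # H3K27me3 flags enriched on planted CpGs at the configured odds ratio
    p0 = config.h3k27_background
    odds1 = config.h3k27_odds_ratio * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    flag = rng.random(n) < p0
    planted_pos = cpg_ids.get_indexer(planted)
    flag[planted_pos] = rng.random(n_planted) < p1

    # compositions: B-dominant, drifting up at t2
    samples, comp_rows, meta_rows = [], [], []
    for p in range(config.n_patients):
        pid = f"P{p:03d}"
        b1 = float(rng.uniform(config.b_fraction_min, config.b_fraction_max))
        b2 = min(b1 + float(rng.uniform(0.0, config.b_fraction_gain_max)),
                 max(b1, 0.97))
        for tp, b_frac in (("t1", b1), ("t2", b2)):
            rest = rng.dirichlet(np.ones(4)) * (1.0 - b_frac)
            comp = np.concatenate([[b_frac], rest])
            sid = f"{pid}_{tp}"
            samples.append(sid)
            comp_rows.append(comp)
            meta_rows.append((sid, pid, tp, False))
    compositions = pd.DataFrame(comp_rows, index=pd.Index(samples, name="sample_id"),
                                columns=list(CELL_TYPES))
    if not np.allclose(compositions.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("composition rows must sum to 1")
    metadata = pd.DataFrame(meta_rows, columns=["sample_id", "patient_id",
                                                "timepoint", "sorted_flag"]
                            ).set_index("sample_id")

    R = prof.to_numpy(float)  # cpgs x 5
    values = {}
    for sid, comp in zip(samples, comp_rows):
        beta = R @ comp
        if metadata.loc[sid, "timepoint"] == "t2":
            beta = beta + delta.to_numpy()
        if config.noise_sd > 0:
            beta = beta + rng.normal(0.0, config.noise_sd, size=n)
        values[sid] = np.clip(beta, 0.0, 1.0)
    betas = BetaMatrix(pd.DataFrame(values, index=cpg_ids), metadata)

    # annotation + synthetic peaks: 1 kb-spaced probes on one chromosome,
    # a 101 bp peak centered on every flagged probe
    pos = 500 + 1000 * np.arange(n)
    annotation = pd.DataFrame({
        "cpg_id": cpg_ids,
        "chrom": "1",
        "pos": pos,
        "gene_symbols": [f"GENE{i // 20:05d}" for i in range(n)],
        "h3k27me3_flag": flag,
    })
    flagged_pos = pos[flag]
    peaks = pd.DataFrame({
        "chrom": "1",
        "start": flagged_pos - 1 - 50,
        "end": flagged_pos - 1 + 51,
    })

    truth = GroundTruth(
        true_compositions=compositions,
        true_progression_cpgs=pd.DataFrame({
            "cpg_id": planted,
            "direction": np.where(up, "up", "down"),
            "effect": effects,
            "h3k27me3_flag": flag[planted_pos],
        }).set_index("cpg_id"),
    )
    return MethylationCohort(betas=betas, reference=reference,
                             annotation=annotation, peaks=peaks, truth=truth)


# ---------------------------------------------------------------------------
# naive / memory B-cell references
# ---------------------------------------------------------------------------

@dataclass
class BCellReferences:
    naive: pd.DataFrame
    memory: pd.DataFrame
    development_cpgs: pd.DataFrame  # cpg_id index, column "delta" (memory - naive)


def simulate_bcell_references(
    config: SimulationConfig,
    cohort: MethylationCohort,
    n_samples_per_group: int = 6,
    dev_effect: tuple[float, float] = (0.12, 0.30),
    n_extra_dev: int = 300,
    rng: np.random.Generator | None = None,
) -> BCellReferences:
    """Naive and memory B-cell reference matrices tied to a cohort.

    The naive profile is the cohort's B-cell reference column.  Memory
    differs from naive at (a) the planted progression CpGs, in the *same
    direction* as the planted progression delta (the developmental
    concordance the analysis should recover), and (b) ``n_extra_dev``
    unrelated CpGs with random directions.  Six replicate samples per group
    are emitted with the cohort's noise sd.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    prof = cohort.reference.profiles
    naive_mean = prof["B"].copy()
    truth = cohort.truth.true_progression_cpgs
    assert truth is not None

    dev_delta = pd.Series(0.0, index=prof.index)
    sign = np.where(truth["direction"].to_numpy() == "up", 1.0, -1.0)
    dev_delta.loc[truth.index] = sign * rng.uniform(*dev_effect, size=len(truth))
    extra_pool = prof.index.difference(truth.index)
    extra = pd.Index(rng.choice(extra_pool.to_numpy(), size=n_extra_dev, replace=False))
    dev_delta.loc[extra] = rng.choice([-1.0, 1.0], size=n_extra_dev) * \
        rng.uniform(*dev_effect, size=n_extra_dev)
    memory_mean = (naive_mean + dev_delta).clip(0.0, 1.0)

    def _replicates(mean: pd.Series, prefix: str) -> pd.DataFrame:
        cols = {}
        for i in range(n_samples_per_group):
            noise = rng.normal(0.0, config.noise_sd, size=len(mean))
            cols[f"{prefix}{i}"] = np.clip(mean.to_numpy() + noise, 0.0, 1.0)
        return pd.DataFrame(cols, index=mean.index)

    dev = pd.DataFrame({"delta": dev_delta[dev_delta != 0.0]})
    dev.index.name = "cpg_id"
    return BCellReferences(
        naive=_replicates(naive_mean, "naive"),
        memory=_replicates(memory_mean, "memory"),
        development_cpgs=dev,
    )


def config_to_dict(config: SimulationConfig) -> dict:
    """Plain-dict view of a config (for echoing into run outputs)."""
    d = asdict(config)
    d["category_probs"] = list(d["category_probs"])
    return d
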