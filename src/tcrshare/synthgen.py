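"""Synthetic repertoire and single-cell data with known ground truth.

The generator emulates the statistical structure of a two-strain TCRα CDR3
repertoire comparison so every stage of the pipeline is testable without
any sequencing download:

* skewed clone sizes from a power-law rank-abundance model p_i ∝ i^(−α),
* a pair of strain repertoires sharing a tunable fraction ρ of clone
  identities, with lognormal noise on the shared-clone frequencies,
* per-mouse / per-replicate multinomial read sampling (3 mice per strain,
  2 biological × 2 technical replicates, matching the study design the
  pipeline is meant for),
* anchored amplicon reads (V-anchor + CDR3 + J-anchor) with iid
  substitution errors,
* small single-cell datasets with cluster structure, planted marker
  genes, designated mitochondrial genes, QC-bait cells, and per-cell
  clonotype labels shared across two strain-labelled datasets.

Every quantity the estimators later recover (true MII, true diversity
profile, marker effect sizes, cluster and clonotype assignments) is
recorded in a truth ledger computed exactly from the generating
distributions.  Identical config + seed gives bit-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .diversity import DEFAULT_Q_GRID, ens_from_frequencies
from .repcore import Clonotype, RepertoireSample
from .repio import AnchorConfig, translate_cdr3
from .similarity import mii_from_frequencies

# codons of the standard code minus the three stop codons
_BASES = "ACGT"
_CODONS = [
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in {"TAA", "TAG", "TGA"}
]


@dataclass
class ScParams:
    """Shape of one simulated single-cell dataset."""

    k_clusters: int = 3
    n_cells: int = 600
    n_genes: int = 2000
    n_marker_genes: int = 20
    marker_log2fc: float = 2.0
    mean_depth: int = 5000
    n_mito_genes: int = 10
    nb_dispersion: float = 2.0
    n_qc_bait_cells: int = 6


@dataclass
class SimConfig:
    """Study-condition parameters of the two-strain repertoire simulation.

    Defaults mirror the conditions the analysis targets: 1000 clones per
    strain with power-law skew α=1; 75% of clone identities shared between
    strains (≈25% strain-private); lognormal jitter σ=1.5 on shared-clone
    frequencies, which puts the true repertoire overlap (MII) in the
    0.3–0.7 band observed between Treg-deficient and healthy repertoires;
    25 000 reads per replicate with 3 mice/strain and 2 biological × 2
    technical replicates.
    """

    n_clones: int = 1000
    alpha: float = 1.0
    shared_fraction: float = 0.75
    shared_noise_sigma: float = 1.5
    reads_per_sample: int = 25_000
    read_error_rate: float = 0.001
    n_mice_per_strain: int = 3
    n_bio_replicates: int = 2
    n_tech_replicates: int = 2
    cdr3_min_codons: int = 4
    cdr3_max_codons: int = 10
    sc_params: ScParams = field(default_factory=ScParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must be in [0, 1]")
        if self.shared_noise_sigma < 0:
            raise ValueError("shared_noise_sigma must be non-negative")
        if not 0 <= self.read_error_rate < 1:
            raise ValueError("read_error_rate must be in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth of one simulated strain pair."""

    p: dict[str, float]  # clone cdr3_nt -> true frequency, strain A
    q: dict[str, float]  # strain B
    shared_clones: list[str]
    true_mii: float
    q_grid: list[float]
    true_profile_a: list[float]
    true_profile_b: list[float]

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["q_grid"] = ["inf" if math.isinf(q) else q for q in self.q_grid]
        Path(path).write_text(json.dumps(payload, indent=1))


def sample_clone_distribution(
    n_clones: int, alpha: float, seed: int | None = None
) -> np.ndarray:
    """Power-law rank-abundance frequency vector p_i ∝ i^(−α), normalized.

    α=0 gives a uniform repertoire.  A seed permutes clone labels only: the
    multiset of frequencies is unchanged.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    ranks = np.arange(1, n_clones + 1, dtype=float)
    weights = ranks**-alpha
    p = weights / weights.sum()
    if seed is not None:
        rng = np.random.default_rng(seed)
        p = rng.permutation(p)
    return p


def _random_cdr3(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_CODONS), size=n_codons)
    return "".join(_CODONS[i] for i in idx)


def make_clone_pool(
    n: int,
    rng: np.random.Generator,
    min_codons: int = 4,
    max_codons: int = 10,
    forbidden: tuple[str, ...] = (),
) -> list[str]:
    """``n`` distinct productive CDR3 nucleotide sequences.

    Stop-free by construction (codons drawn from the 61 sense codons);
    sequences containing any ``forbidden`` substring (e.g. the extraction
    anchors) are rejected so simulated reads stay unambiguous.
    """
    pool: list[str] = []
    seen: set[str] = set()
    while len(pool) < n:
        n_codons = int(rng.integers(min_codons, max_codons + 1))
        seq = _random_cdr3(rng, n_codons)
        if seq in seen or any(f in seq for f in forbidden):
            continue
        seen.add(seq)
        pool.append(seq)
    return pool


def simulate_pair(cfg: SimConfig) -> tuple[dict[str, float], dict[str, float], SimTruth]:
    """Two strain-level clonotype distributions with a known shared core.

    round(ρ·n_clones) clone identities are shared.  Strain A frequencies
    follow the rank-abundance law; strain B gets its own seeded rank
    assignment, then its shared clones are overridden with the strain-A
    frequency times lognormal noise exp(N(0, σ²)) and the whole vector is
    renormalized.  ρ=1, σ=0 makes the distributions equal up to
    renormalization rounding (true MII 1); ρ=0 makes them disjoint
    (true MII 0).
    """
    rng = np.random.default_rng(cfg.seed)
    n_shared = round(cfg.shared_fraction * cfg.n_clones)
    n_total_ids = 2 * cfg.n_clones - n_shared
    anchors = AnchorConfig()
    pool = make_clone_pool(
        n_total_ids, rng, cfg.cdr3_min_codons, cfg.cdr3_max_codons,
        forbidden=(anchors.v_anchor, anchors.j_anchor),
    )
    shared_ids = pool[:n_shared]
    private_a = pool[n_shared : cfg.n_clones]
    private_b = pool[cfg.n_clones :]
    clones_a = shared_ids + private_a
    clones_b = shared_ids + private_b

    p_vec = sample_clone_distribution(cfg.n_clones, cfg.alpha)
    p_vec = rng.permutation(p_vec)
    q_base = rng.permutation(sample_clone_distribution(cfg.n_clones, cfg.alpha))
    q_vec = q_base.copy()
    if n_shared:
        noise = np.exp(rng.normal(0.0, cfg.shared_noise_sigma, size=n_shared))
        q_vec[:n_shared] = p_vec[:n_shared] * noise
    q_vec = q_vec / q_vec.sum()

    p = dict(zip(clones_a, p_vec.tolist()))
    q = dict(zip(clones_b, q_vec.tolist()))
    truth = _truth_for_pair(p, q, shared_ids)
    return p, q, truth


def _truth_for_pair(
    p: dict[str, float], q: dict[str, float], shared: list[str]
) -> SimTruth:
    union = sorted(set(p) | set(q))
    pv = np.array([p.get(c, 0.0) for c in union])
    qv = np.array([q.get(c, 0.0) for c in union])
    true_mii = mii_from_frequencies(pv, qv).value
    grid = list(DEFAULT_Q_GRID)
    prof_a = [ens_from_frequencies(np.array(list(p.values())), x) for x in grid]
    prof_b = [ens_from_frequencies(np.array(list(q.values())), x) for x in grid]
    return SimTruth(
        p=p, q=q, shared_clones=list(shared), true_mii=true_mii,
        q_grid=grid, true_profile_a=prof_a, true_profile_b=prof_b,
    )


def sample_reads(
    freqs: dict[str, float],
    n: int,
    seed: int,
    sample_id: str = "sim",
    strain: str = "",
    organ: str = "LN",
    subset: str = "",
    replicate: str = "",
) -> RepertoireSample:
    """Multinomial read sample of size ``n`` from a clonotype distribution."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    clones = sorted(freqs)
    probs = np.array([freqs[c] for c in clones])
    draws = rng.multinomial(n, probs / probs.sum())
    counts = {
        Clonotype(cdr3_nt=c, cdr3_aa=translate_cdr3(c), v_call="Va2", j_call="Ja2"): int(k)
        for c, k in zip(clones, draws) if k > 0
    }
    return RepertoireSample(
        sample_id=sample_id, counts=counts, strain=strain, organ=organ,
        subset=subset, replicate=replicate,
    )


def reads_to_fastq(
    sample: RepertoireSample,
    path: str | Path,
    anchors: AnchorConfig | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
) -> int:
    """Write anchored amplicon reads for a clonotype count table as FASTQ.

    Each clonotype with count k yields k reads v_anchor + cdr3 + j_anchor
    with iid substitution errors at ``error_rate`` per base.  At error rate
    0 the extraction round-trip recovers the table exactly.  Returns the
    number of reads written.
    """
    if anchors is None:
        anchors = AnchorConfig()
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_written = 0
    path = Path(path)
    with open(path, "w") as fh:
        ranked = sorted(sample.counts.items(), key=lambda kv: (-kv[1], kv[0].cdr3_nt))
        for clone, count in ranked:
            template = anchors.v_anchor + clone.cdr3_nt + anchors.j_anchor
            for _ in range(count):
                seq = template
                if error_rate > 0:
                    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                    hits = np.flatnonzero(rng.random(arr.size) < error_rate)
                    for pos in hits:
                        current = chr(arr[pos])
                        options = [b for b in _BASES if b != current]
                        arr[pos] = ord(options[int(rng.integers(0, 3))])
                    seq = arr.tobytes().decode()
                n_written += 1
                fh.write(f"@read{n_written}\n{seq}\n+\n{'I' * len(seq)}\n")
    return n_written


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[dict[str, list[RepertoireSample]], SimTruth]:
    """Replicate-level repertoires for a full two-strain cohort.

    Returns ``{strain: [replicate samples...]}`` for strains "Sf" and
    "healthy", with ``n_mice_per_strain`` mice each contributing
    ``n_bio_replicates × n_tech_replicates`` multinomial read samples of
    ``reads_per_sample`` reads, plus the generating-pair truth ledger.
    Sample ids encode mouse/replicate provenance; replicate samples of one
    mouse share its metadata so they can be pooled with merge_replicates.
    """
    p, q, truth = simulate_pair(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    child_seeds = iter(s.generate_state(1)[0] % (2**31) for s in ss.spawn(
        2 * cfg.n_mice_per_strain * cfg.n_bio_replicates * cfg.n_tech_replicates
    ))
    cohort: dict[str, list[RepertoireSample]] = {}
    for strain, freqs in (("Sf", p), ("healthy", q)):
        samples = []
        for mouse in range(1, cfg.n_mice_per_strain + 1):
            for bio in range(1, cfg.n_bio_replicates + 1):
                for tech in range(1, cfg.n_tech_replicates + 1):
                    rep_id = f"{strain}_m{mouse}_b{bio}_t{tech}"
                    samples.append(
                        sample_reads(
                            freqs, cfg.reads_per_sample, seed=int(next(child_seeds)),
                            sample_id=rep_id, strain=strain, organ="LN",
                            subset=f"m{mouse}", replicate=f"b{bio}t{tech}",
                        )
                    )
        cohort[strain] = samples
    return cohort, truth


# --- single-cell simulation ---------------------------------------------------


@dataclass
class ScTruth:
    """Ground truth for one simulated single-cell dataset."""

    cluster: list[str]
    clonotype: list[str]
    marker_genes: dict[str, list[str]]  # cluster -> planted marker gene ids
    marker_log2fc: float
    qc_bait_barcodes: list[str]


def simulate_sc(
    cfg: SimConfig,
    strain: str = "Sf",
    clone_freqs: dict[str, float] | None = None,
    seed_offset: int = 0,
) -> tuple["ScDataset", ScTruth]:
    """One single-cell dataset with clusters, planted markers and clonotypes.

    Counts are negative-binomial around per-gene lognormal base rates;
    marker genes are up-shifted by 2^log2fc in their own cluster; the first
    ``n_mito_genes`` genes are designated mitochondrial ("mt-*") at trace
    expression.  A handful of QC-bait cells (too few detected genes, or
    mitochondrial fraction above the cap) is appended to exercise the QC
    gate; their barcodes are recorded in the truth.  ``marker_log2fc=0``
    yields a global-null dataset for calibration.

    Per-cell clonotypes are drawn from ``clone_freqs`` (defaults to a fresh
    power-law repertoire), so two calls sharing a distribution produce
    strain datasets with genuinely shared clonotypes.
    """
    from .sclink import ScDataset  # local import to avoid a cycle

    sp = cfg.sc_params
    rng = np.random.default_rng(cfg.seed + 7_001 + seed_offset)

    gene_ids = [f"mt-{i}" for i in range(1, sp.n_mito_genes + 1)] + [
        f"gene{i}" for i in range(1, sp.n_genes - sp.n_mito_genes + 1)
    ]
    mito_genes = set(gene_ids[: sp.n_mito_genes])

    base = np.exp(rng.normal(0.0, 1.0, size=sp.n_genes))
    base[: sp.n_mito_genes] *= 0.02  # trace mitochondrial expression
    base /= base.sum()

    clusters = [f"c{1 + i % sp.k_clusters}" for i in range(sp.n_cells)]
    marker_genes: dict[str, list[str]] = {}
    free = np.arange(sp.n_mito_genes, sp.n_genes)
    n_markers_total = sp.k_clusters * sp.n_marker_genes
    if n_markers_total > free.size:
        raise ValueError(
            f"{n_markers_total} marker genes requested but only {free.size} "
            "non-mitochondrial genes available"
        )
    picks = rng.choice(free, size=n_markers_total, replace=False)
    for k in range(sp.k_clusters):
        ids = picks[k * sp.n_marker_genes : (k + 1) * sp.n_marker_genes]
        marker_genes[f"c{k + 1}"] = [gene_ids[i] for i in ids]

    fold = 2.0**sp.marker_log2fc
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    marker_idx = {
        cl: np.array([gene_index[g] for g in genes], dtype=int)
        for cl, genes in marker_genes.items()
    }
    counts = np.zeros((sp.n_genes, sp.n_cells), dtype=np.int64)
    disp = sp.nb_dispersion
    for j, cl in enumerate(clusters):
        rates = base.copy()
        if sp.marker_log2fc != 0:
            rates[marker_idx[cl]] *= fold
            rates /= rates.sum()
        mu = rates * sp.mean_depth
        # NB with mean mu and dispersion r: p = r/(r+mu)
        p_nb = disp / (disp + mu)
        counts[:, j] = rng.negative_binomial(disp, p_nb)

    if clone_freqs is None:
        p_vec = sample_clone_distribution(200, cfg.alpha)
        pool = make_clone_pool(200, rng, cfg.cdr3_min_codons, cfg.cdr3_max_codons)
        clone_freqs = dict(zip(pool, p_vec.tolist()))
    clone_ids = sorted(clone_freqs)
    probs = np.array([clone_freqs[c] for c in clone_ids])
    probs = probs / probs.sum()
    clono = [clone_ids[i] for i in rng.choice(len(clone_ids), size=sp.n_cells, p=probs)]

    barcodes = [f"{strain}-cell{j + 1}" for j in range(sp.n_cells)]

    # QC-bait cells: half with too few detected genes, half with high mito load
    n_bait = sp.n_qc_bait_cells
    bait_counts = np.zeros((sp.n_genes, n_bait), dtype=np.int64)
    bait_barcodes = []
    for j in range(n_bait):
        if j % 2 == 0:  # sparse cell: ~150 detected genes (fewer on tiny matrices)
            n_detect = min(150, max(sp.n_genes // 4, 1))
            genes = rng.choice(sp.n_genes, size=n_detect, replace=False)
            bait_counts[genes, j] = 1
        else:  # mito-heavy cell
            bait_counts[:, j] = rng.poisson(base * sp.mean_depth)
            bait_counts[: sp.n_mito_genes, j] += int(sp.mean_depth * 0.2)
        bait_barcodes.append(f"{strain}-bait{j + 1}")

    data = ScDataset(
        counts=np.concatenate([counts, bait_counts], axis=1),
        gene_ids=gene_ids,
        barcodes=barcodes + bait_barcodes,
        mito_genes=mito_genes,
        cluster_label=clusters + ["bait"] * n_bait,
        clonotype=clono + [None] * n_bait,
        strain=strain,
    )
    truth = ScTruth(
        cluster=list(clusters),
        clonotype=list(clono),
        marker_genes=marker_genes,
        marker_log2fc=sp.marker_log2fc,
        qc_bait_barcodes=bait_barcodes,
    )
    return data, truth


def simulate_sc_pair(cfg: SimConfig) -> tuple[list, list[ScTruth]]:
    """Two strain-labelled single-cell datasets sharing part of the repertoire."""
    p, q, _ = simulate_pair(cfg)
    data_a, truth_a = simulate_sc(cfg, strain="Sf", clone_freqs=p, seed_offset=0)
    data_b, truth_b = simulate_sc(cfg, strain="healthy", clone_freqs=q, seed_offset=1)
    return [data_a, data_b], [truth_a, truth_b]
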