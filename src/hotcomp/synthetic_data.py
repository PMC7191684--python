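"""Synthetic inputs with the statistical structure the pipeline assumes.

Generates a drift tree, tree-structured hotspot presence/absence (two-state
Markov gain/loss along branches), autocorrelated log-rate landscapes with
hotspot intensity spikes and Poisson SNP spacing, emulated MCMC traces, gene
and repeat annotations, population metadata, an F_ST proxy, and a genotype
homozygosity table with injected rate effects — everything the downstream
modules consume, reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    GeneModel,
    GenomeLayout,
    Interval,
    write_bed,
    write_genome_layout,
    write_gff_genes,
    write_ldhat_rates,
    write_matrix_tsv,
    write_population_meta,
    write_rate_trace,
)
from .phylo_trait import DriftTree
from .ratemap import PopulationMeta, RateMap, RateTrace

__all__ = [
    "SimConfig",
    "simulate_drift_tree",
    "simulate_hotspot_landscape",
    "simulate_ratemap",
    "simulate_annotations",
    "simulate_genotype_table",
    "simulate_population_meta",
    "fst_proxy",
    "simulate_dataset",
    "LandscapeResult",
    "GenotypeSim",
]


@dataclass
class SimConfig:
    seed: int = 0
    populations: list[str] = field(
        default_factory=lambda: [f"pop{i + 1}" for i in range(10)]
    )
    tree_newick: str | None = None
    tree_branch_mean: float = 0.2       # drift units, for simulated trees
    chrom_length: int = 2_000_000
    chrom_name: str = "chr1"
    snp_density: float = 1.0 / 200.0    # SNPs per bp
    # background landscape: rho in Morgans/bp on the log scale
    log_rate_mean: float = float(np.log(1e-3))
    log_rate_sd: float = 0.8
    autocorr_length_bp: float = 50_000.0
    # hotspots
    hotspot_density_per_mb: float = 20.0
    hotspot_length_mean: float = 2000.0
    hotspot_length_sd: float = 400.0
    hotspot_intensity: float = 10.0
    gain_rate: float = 0.5              # per drift unit
    loss_rate: float = 0.5
    birth_rate_per_mb: float = 0.0      # branch-specific new loci
    p_tss_bias: float = 0.0
    # trace emulation
    trace_n_samples: int = 100
    trace_rel_ci_width: float = 0.1
    # annotations
    n_genes: int = 100
    gene_length_mean: float = 3000.0
    exons_per_gene: int = 3
    repeat_fractions: dict = field(
        default_factory=lambda: {
            "retroelement": 0.10,
            "dna_transposon": 0.02,
            "other_repeat": 0.03,
        }
    )
    repeat_length_mean: float = 500.0
    # genotype/GLM block
    n_mutations: int = 5
    glm_intercept: float = 2.0
    glm_effects: list[float] = field(
        default_factory=lambda: [5.0, 0.0, 0.0, 0.0, 0.0]
    )
    glm_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        if len(self.populations) < 2:
            raise ValueError("need >= 2 populations")
        for name, value in (
            ("snp_density", self.snp_density),
            ("hotspot_density_per_mb", self.hotspot_density_per_mb),
            ("gain_rate", self.gain_rate),
            ("loss_rate", self.loss_rate),
            ("birth_rate_per_mb", self.birth_rate_per_mb),
            ("hotspot_intensity", self.hotspot_intensity),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.p_tss_bias <= 1.0:
            raise ValueError("p_tss_bias must be in [0, 1]")
        if sum(self.repeat_fractions.values()) > 1.0:
            raise ValueError("repeat fractions exceed the genome")
        if len(self.glm_effects) != self.n_mutations:
            raise ValueError("glm_effects must have n_mutations entries")

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout({self.chrom_name: self.chrom_length})

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------

def simulate_drift_tree(config: SimConfig, rng: np.random.Generator) -> DriftTree:
    """Random rooted bifurcating tree by sequential joins, exponential
    branch lengths (mean ``tree_branch_mean`` drift units)."""
    if config.tree_newick:
        return DriftTree.from_newick(config.tree_newick)
    nodes = list(config.populations)
    newick = {n: n for n in nodes}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        la, lb = rng.exponential(config.tree_branch_mean, size=2)
        name = f"({newick[a]}:{la:.6f},{newick[b]}:{lb:.6f})"
        nodes = [n for n in nodes if n not in (a, b)] + [name]
        newick[name] = name
    return DriftTree.from_newick(nodes[0] + ";")


# ---------------------------------------------------------------------------
# hotspot landscape along the tree
# ---------------------------------------------------------------------------

@dataclass
class LandscapeResult:
    ancestral: list[Interval]
    loci: list[Interval]                 # all loci incl. branch births
    presence: pd.DataFrame               # populations x loci (bool)
    tip_sets: dict[str, list[Interval]]


def _draw_locus(
    config: SimConfig,
    rng: np.random.Generator,
    tss: Sequence[Interval] | None,
) -> Interval:
    length = max(int(round(rng.normal(config.hotspot_length_mean,
                                      config.hotspot_length_sd))), 200)
    if length > config.chrom_length:
        raise ValueError("hotspot longer than chromosome")
    if tss and rng.random() < config.p_tss_bias:
        anchor = tss[int(rng.integers(len(tss)))]
        center = (anchor.start + anchor.end) // 2
        start = int(np.clip(center - length // 2, 0,
                            config.chrom_length - length))
    else:
        start = int(rng.integers(0, config.chrom_length - length + 1))
    return Interval(config.chrom_name, start, start + length)


def _transition(state: np.ndarray, t: float, gain: float, loss: float,
                rng: np.random.Generator) -> np.ndarray:
    """Two-state Markov evolution of presence over a branch of length t."""
    s = gain + loss
    if s == 0 or t == 0:
        return state.copy()
    decay = np.exp(-s * t)
    p_stay_present = gain / s + loss / s * decay
    p_become_present = gain / s * (1.0 - decay)
    u = rng.random(state.size)
    return np.where(state, u < p_stay_present, u < p_become_present)


def simulate_hotspot_landscape(
    config: SimConfig,
    tree: DriftTree,
    rng: np.random.Generator,
    tss: Sequence[Interval] | None = None,
) -> LandscapeResult:
    """Ancestral Poisson hotspot loci evolved along the tree by gain/loss.

    Loci are present at the root; presence flips along each branch as a
    two-state Markov process with the configured gain/loss rates.  New loci
    may additionally be born on branches (``birth_rate_per_mb``) and are
    subject to the same loss process below their origin.
    """
    n_anc = rng.poisson(
        config.hotspot_density_per_mb * config.chrom_length / 1e6
    )
    loci = [_draw_locus(config, rng, tss) for _ in range(n_anc)]
    dtree = tree._tree
    state_at: dict = {dtree.seed_node: np.ones(n_anc, dtype=bool)}
    born_at: dict = {dtree.seed_node: n_anc}
    tip_state: dict[str, np.ndarray] = {}
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue
        t = node.edge.length or 0.0
        parent_state = state_at[node.parent_node]
        # pad parent state for loci born after it was recorded
        if parent_state.size < len(loci):
            parent_state = np.concatenate(
                [parent_state,
                 np.zeros(len(loci) - parent_state.size, dtype=bool)]
            )
        # ancestral loci can be lost and regained; branch-born loci can only
        # be lost outside the lineage where they arose
        state = np.concatenate(
            [
                _transition(parent_state[:n_anc], t, config.gain_rate,
                            config.loss_rate, rng),
                _transition(parent_state[n_anc:], t, 0.0,
                            config.loss_rate, rng),
            ]
        )
        n_born = rng.poisson(
            config.birth_rate_per_mb * config.chrom_length / 1e6 * t
        )
        if n_born:
            for _ in range(n_born):
                loci.append(_draw_locus(config, rng, tss))
            state = np.concatenate([state, np.ones(n_born, dtype=bool)])
        state_at[node] = state
        if node.is_leaf():
            tip_state[node.taxon.label] = state
    n_total = len(loci)
    presence = pd.DataFrame(
        False,
        index=tree.taxa,
        columns=[f"locus{i + 1}" for i in range(n_total)],
        dtype=bool,
    )
    tip_sets: dict[str, list[Interval]] = {}
    for pop in tree.taxa:
        state = tip_state.get(pop, np.zeros(n_total, dtype=bool))
        if state.size < n_total:
            state = np.concatenate(
                [state, np.zeros(n_total - state.size, dtype=bool)]
            )
        presence.loc[pop] = state
        tip_sets[pop] = [loci[i] for i in np.flatnonzero(state)]
    return LandscapeResult(
        ancestral=loci[:n_anc],
        loci=loci,
        presence=presence,
        tip_sets=tip_sets,
    )


# ---------------------------------------------------------------------------
# rate map + trace
# ---------------------------------------------------------------------------

def simulate_ratemap(
    config: SimConfig,
    hotspots: Sequence[Interval],
    rng: np.random.Generator,
    population: str = "",
    with_trace: bool = False,
) -> tuple[RateMap, RateTrace | None]:
    """SNP positions ~ Poisson(density); log background rate is an AR(1)
    Gaussian process over interval midpoints; rates inside hotspots are
    multiplied by the intensity factor; optional lognormal-free trace
    samples around each point estimate (truncated normal at 0)."""
    L = config.chrom_length
    for h in hotspots:
        if h.length > L:
            raise ValueError("hotspot longer than chromosome")
    n_snps = max(int(rng.poisson(L * config.snp_density)), 2)
    positions = np.sort(rng.choice(L, size=min(n_snps, L), replace=False))
    while positions.size < 2:
        positions = np.sort(rng.choice(L, size=2, replace=False))
    mids = (positions[:-1] + positions[1:]) / 2.0
    gaps = np.diff(mids)
    phi = np.exp(-gaps / config.autocorr_length_bp)
    z = rng.standard_normal(mids.size)
    x = np.empty(mids.size)
    x[0] = z[0]
    for i in range(1, mids.size):
        x[i] = phi[i - 1] * x[i - 1] + np.sqrt(1.0 - phi[i - 1] ** 2) * z[i]
    rates = np.exp(config.log_rate_mean + config.log_rate_sd * x)
    if hotspots:
        from .comparison import merge_intervals

        merged = merge_intervals(
            [h for h in hotspots if h.chrom == config.chrom_name]
        )
        if merged:
            # multiply each interval's rate by the intensity factor in
            # proportion to its overlap with hotspot bp, so per-interval rho
            # integrates the underlying spiked landscape
            starts = np.array([h.start for h in merged])
            ends = np.array([h.end for h in merged])
            cover = np.zeros(rates.size)
            left = positions[:-1]
            right = positions[1:]
            for hs, he in zip(starts, ends):
                ov = np.minimum(right, he) - np.maximum(left, hs)
                cover += np.clip(ov, 0, None)
            frac = cover / (right - left)
            rates = rates * (1.0 + (config.hotspot_intensity - 1.0) * frac)
    ratemap = RateMap(
        chrom=config.chrom_name,
        positions=positions,
        rates=rates,
        population=population,
    )
    trace = None
    if with_trace:
        sigma = config.trace_rel_ci_width * rates / 3.92
        samples = rng.normal(
            rates[:, None], sigma[:, None],
            size=(rates.size, config.trace_n_samples),
        )
        trace = RateTrace(samples=np.clip(samples, 0.0, None))
    return ratemap, trace


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def simulate_annotations(
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[GeneModel], dict[str, list[Interval]]]:
    """Non-overlapping genes with exon/intron structure plus labeled repeat
    tracks hitting the configured genome fractions."""
    L = config.chrom_length
    genes: list[GeneModel] = []
    if config.n_genes > 0:
        total_gene_bp = config.n_genes * config.gene_length_mean
        if total_gene_bp > 0.8 * L:
            raise ValueError("requested gene coverage infeasible")
        # place genes left to right with random gaps
        mean_gap = (L - total_gene_bp) / (config.n_genes + 1)
        cursor = 0
        for g in range(config.n_genes):
            gap = int(rng.exponential(mean_gap)) + 1
            length = max(int(rng.normal(config.gene_length_mean,
                                        config.gene_length_mean / 5)), 300)
            start = cursor + gap
            end = start + length
            if end > L:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            k = max(int(rng.poisson(config.exons_per_gene - 1)) + 1, 1)
            cuts = np.sort(rng.choice(
                np.arange(1, length), size=min(2 * k - 2, length - 1),
                replace=False,
            ))
            bounds = np.concatenate([[0], cuts, [length]])
            exons = tuple(
                (start + int(bounds[i]), start + int(bounds[i + 1]))
                for i in range(0, bounds.size - 1, 2)
            )
            genes.append(
                GeneModel(
                    gene_id=f"gene{g + 1}",
                    chrom=config.chrom_name,
                    start=start,
                    end=end,
                    strand=strand,
                    exons=exons,
                )
            )
            cursor = end
    repeats: dict[str, list[Interval]] = {}
    from .enrichment import random_hotspot_set

    for cls, fraction in config.repeat_fractions.items():
        target_bp = int(round(fraction * L))
        lengths: list[int] = []
        acc = 0
        while acc < target_bp:
            ln = max(int(rng.exponential(config.repeat_length_mean)), 50)
            ln = min(ln, target_bp - acc) if target_bp - acc >= 50 else (
                target_bp - acc
            )
            if ln <= 0:
                break
            lengths.append(ln)
            acc += ln
        template = [
            Interval(config.chrom_name, 0, ln) for ln in lengths if ln > 0
        ]
        repeats[cls] = random_hotspot_set(template, config.layout, rng)
    return genes, repeats


# ---------------------------------------------------------------------------
# metadata / F_ST proxy / genotype table
# ---------------------------------------------------------------------------

def simulate_population_meta(
    config: SimConfig, rng: np.random.Generator
) -> dict[str, PopulationMeta]:
    out = {}
    for pop in config.populations:
        out[pop] = PopulationMeta(
            name=pop,
            ne=float(rng.uniform(4000, 62_000)),
            inbreeding_f=float(rng.uniform(0.0, 0.9)),
            sample_size=int(rng.integers(4, 31)),
        )
    return out


def fst_proxy(tree: DriftTree) -> pd.DataFrame:
    """Monotone drift-to-differentiation map: F_ST = 1 - exp(-distance)."""
    d = tree.patristic_matrix()
    fst = 1.0 - np.exp(-d)
    np.fill_diagonal(fst, 0.0)
    return pd.DataFrame(fst, index=tree.taxa, columns=tree.taxa)


@dataclass
class GenotypeSim:
    frequencies: pd.DataFrame     # populations x mutations, hom-alt freq
    response: pd.Series           # per-population median-r response
    intercept: float
    effects: np.ndarray


def simulate_genotype_table(
    config: SimConfig, rng: np.random.Generator
) -> GenotypeSim:
    """Hom-alt frequencies in [0, 1] with an injected linear rate effect:
    y = b0 + X b + eps."""
    n_pop = len(config.populations)
    n_mut = config.n_mutations
    X = rng.uniform(0.0, 1.0, size=(n_pop, n_mut))
    zero_mask = rng.random((n_pop, n_mut)) < 0.3   # many real cells are 0
    X = np.where(zero_mask, 0.0, X)
    effects = np.asarray(config.glm_effects, dtype=float)
    y = (
        config.glm_intercept
        + X @ effects
        + rng.normal(0.0, config.glm_noise_sd, size=n_pop)
    )
    freq = pd.DataFrame(
        X,
        index=config.populations,
        columns=[f"mut{j + 1}" for j in range(n_mut)],
    )
    return GenotypeSim(
        frequencies=freq,
        response=pd.Series(y, index=config.populations, name="median_r"),
        intercept=config.glm_intercept,
        effects=effects,
    )


# ---------------------------------------------------------------------------
# full dataset writer
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig, out_dir) -> dict:
    """Generate and write every input the other subcommands consume.

    Returns the in-memory objects for convenience.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    tree = simulate_drift_tree(config, rng)
    genes, repeats = simulate_annotations(config, rng)
    from .enrichment import derive_flanks

    tss, _tts = derive_flanks(genes, config.layout)
    landscape = simulate_hotspot_landscape(
        config, tree, rng, tss=tss if config.p_tss_bias > 0 else None
    )
    meta = simulate_population_meta(config, rng)
    ratemaps: dict[str, RateMap] = {}
    for pop in config.populations:
        rmap, trace = simulate_ratemap(
            config, landscape.tip_sets[pop], rng, population=pop,
            with_trace=True,
        )
        ratemaps[pop] = rmap
        write_ldhat_rates(rmap, out / f"rates_{pop}_{config.chrom_name}.txt")
        if trace is not None:
            write_rate_trace(trace, out / f"trace_{pop}_{config.chrom_name}.tsv")
        write_bed(
            [
                Interval(h.chrom, h.start, h.end, name=f"{pop}_hs{i + 1}")
                for i, h in enumerate(landscape.tip_sets[pop])
            ],
            out / f"hotspots_{pop}.bed",
        )
    write_genome_layout(config.layout, out / "layout.tsv")
    (out / "tree.nwk").write_text(tree.as_newick() + "\n")
    write_matrix_tsv(fst_proxy(tree), out / "fst.tsv")
    write_population_meta(meta, out / "meta.tsv")
    write_gff_genes(genes, out / "genes.gff3")
    repeat_rows = [
        Interval(iv.chrom, iv.start, iv.end, name=cls)
        for cls, ivs in repeats.items()
        for iv in ivs
    ]
    write_bed(sorted(repeat_rows), out / "repeats.bed")
    geno = simulate_genotype_table(config, rng)
    write_matrix_tsv(geno.frequencies, out / "genotypes.tsv")
    geno.response.to_frame().to_csv(out / "median_r.tsv", sep="\t")
    return {
        "tree": tree,
        "landscape": landscape,
        "meta": meta,
        "ratemaps": ratemaps,
        "genes": genes,
        "repeats": repeats,
        "genotypes": geno,
    }
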