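"""Synthetic-data generator emulating the melatonin root RNA-seq study design.

The real study sequenced three single libraries from rice roots — water
control (M0) and two melatonin doses (M10, M20) — and combined FPKM
fold-change DEG calling, K-means clustering, promoter motif scanning and
GO enrichment. This module fabricates every input that pipeline needs
with recorded ground truth so recovery can be tested:

* a random genome plus non-overlapping single-exon gene models, each
  with a clear 1000-bp upstream promoter on its own strand;
* negative-binomial counts with planted log2 effects (DE truth) and
  planted cluster prototypes laid out on the circle that z-scored
  three-sample profiles live on;
* promoters rewritten to a GC-only alphabet and re-seeded with exact
  IUPAC motif instances at chosen carrier fractions, so that A/T-bearing
  motifs have zero accidental carriers and printed carrier counts are
  exactly constructible;
* gene→GO assignments with planted enriched terms;
* qRT-PCR Ct tables whose ΔΔCt inverts to the planted log2 ratios, and
  truncated-normal root-angle tables.

There are no replicates within a condition, matching the study, so DE
truth is defined by the planted effects rather than by any test.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import helmert

from . import io as mio
from .motifscan import expand_iupac, promoter_intervals, validate_iupac

__all__ = [
    "DEFAULT_MOTIFS",
    "DEPattern",
    "ClusterPrototype",
    "MotifPlan",
    "GOPlan",
    "SimulationSpec",
    "GroundTruth",
    "SyntheticDataset",
    "circular_prototypes",
    "generate_annotation",
    "plant_motifs",
    "generate_counts",
    "generate_go_map",
    "generate_qpcr",
    "generate_gravitropism",
    "random_go_spec",
    "study_dataset",
    "simulate",
]

# The six cis-element consensus strings the pipeline ships as its default
# catalog: ARF binding site, auxin-response element, root tip meristem
# element, root-specific element (RSE) and the two W-box cores.
DEFAULT_MOTIFS: dict[str, str] = {
    "motif1": "TGTCTC",
    "motif2": "TACACAT",
    "motif3": "TATTCT",
    "motif4": "ATATT",
    "motif5": "TTGAC",
    "motif6": "TGACT",
}


@dataclass(frozen=True)
class DEPattern:
    """A planted block of differentially expressed genes."""

    size: int
    direction: str  # "up" or "down"
    log2_effect: float  # magnitude; sign is taken from direction
    conditions: tuple[str, ...] = ("M10", "M20")

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {self.direction!r}")
        if self.size < 0:
            raise ValueError("size must be >= 0")
        if not math.isfinite(self.log2_effect) or self.log2_effect < 0:
            raise ValueError("log2_effect must be a finite magnitude >= 0")

    @property
    def signed_effect(self) -> float:
        return self.log2_effect if self.direction == "up" else -self.log2_effect


@dataclass(frozen=True)
class ClusterPrototype:
    """A planted co-expression cluster: a log2 offset per condition."""

    size: int
    log2_profile: tuple[float, ...]

    def __post_init__(self):
        if self.size < 0:
            raise ValueError("size must be >= 0")
        if not all(math.isfinite(v) for v in self.log2_profile):
            raise ValueError("profile offsets must be finite")


@dataclass(frozen=True)
class MotifPlan:
    """Plant a motif into a fraction of a gene set's promoters."""

    motif_id: str
    iupac: str
    genes: tuple[str, ...] | None = None  # None = every annotated gene
    carrier_fraction: float = 0.0
    n_carriers: int | None = None  # overrides the fraction when given

    def __post_init__(self):
        validate_iupac(self.iupac)
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must be in [0, 1]")
        if self.n_carriers is not None and self.n_carriers < 0:
            raise ValueError("n_carriers must be >= 0")


@dataclass(frozen=True)
class GOPlan:
    """An explicit GO term → gene-set assignment."""

    term: str
    genes: tuple[str, ...]
    enriched: bool = False


def circular_prototypes(
    k: int, n_conditions: int = 3, amplitude: float = 2.0, size: int = 50
) -> tuple[ClusterPrototype, ...]:
    """``k`` evenly spaced cluster prototypes, maximally separated after
    per-gene z-scoring.

    Z-scored profiles over n samples lie on a sphere inside the sum-zero
    hyperplane — a circle when n = 3 — so prototypes placed at equal
    angles in that plane are as far apart as planted patterns can get.
    ``amplitude`` is the root-mean-square log2 deviation of each profile.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_conditions < 3:
        raise ValueError("need >= 3 conditions for distinct circular prototypes")
    basis = helmert(n_conditions)[:2]  # two orthonormal sum-zero directions
    protos = []
    for j in range(k):
        theta = 2 * math.pi * j / k
        pattern = math.sqrt(n_conditions) * (
            math.cos(theta) * basis[0] + math.sin(theta) * basis[1]
        )
        protos.append(ClusterPrototype(size=size, log2_profile=tuple(amplitude * pattern)))
    return tuple(protos)


@dataclass
class SimulationSpec:
    """All knobs of the synthetic study, mirroring its design: three
    single-library conditions, ~10M fragments each, low extra-Poisson
    dispersion since single libraries carry no replicate variance."""

    n_genes: int = 2000
    chrom_length: int = 10_000_000
    promoter_length: int = 1000
    conditions: tuple[str, ...] = ("M0", "M10", "M20")
    library_sizes: Mapping[str, int] | int = 10_000_000
    nb_dispersion: float = 0.05
    gene_length_range: tuple[int, int] = (500, 3000)
    intergenic_gap: int = 100
    expr_meanlog: float = 3.0  # lognormal baseline abundance (per-kb units)
    expr_sdlog: float = 1.0
    planted_expr_range: tuple[float, float] = (20.0, 80.0)
    de_spec: tuple[DEPattern, ...] = ()
    cluster_spec: tuple[ClusterPrototype, ...] = ()
    motif_spec: tuple[MotifPlan, ...] = ()
    go_spec: tuple[GOPlan, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.chrom_length < 1:
            raise ValueError("chrom_length must be >= 1")
        if self.promoter_length < 1:
            raise ValueError("promoter_length must be >= 1")
        if len(set(self.conditions)) != len(self.conditions) or len(self.conditions) < 2:
            raise ValueError("conditions must be >= 2 distinct labels")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        lo, hi = self.gene_length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid gene_length_range")
        for size in self.library_size_map().values():
            if size <= 0:
                raise ValueError("library sizes must be > 0")
        planted = sum(p.size for p in self.de_spec) + sum(c.size for c in self.cluster_spec)
        if planted > self.n_genes:
            raise ValueError(
                f"planted gene sets ({planted}) exceed the gene universe ({self.n_genes})"
            )
        for pattern in self.de_spec:
            unknown = set(pattern.conditions) - set(self.conditions)
            if unknown:
                raise ValueError(f"DE pattern names unknown conditions: {sorted(unknown)}")
        for proto in self.cluster_spec:
            if len(proto.log2_profile) != len(self.conditions):
                raise ValueError("cluster prototype profile length != number of conditions")

    def library_size_map(self) -> dict[str, int]:
        if isinstance(self.library_sizes, Mapping):
            return {c: int(self.library_sizes[c]) for c in self.conditions}
        return {c: int(self.library_sizes) for c in self.conditions}


@dataclass
class GroundTruth:
    """What was planted, for recovery tests downstream."""

    de_up: dict[str, frozenset] = field(default_factory=dict)  # comparison → genes
    de_down: dict[str, frozenset] = field(default_factory=dict)
    cluster_labels: dict[str, int] = field(default_factory=dict)
    motif_carriers: dict[str, frozenset] = field(default_factory=dict)
    enriched_go: frozenset = frozenset()
    baseline_means: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(obj):
            if isinstance(obj, frozenset):
                return sorted(obj)
            raise TypeError(type(obj))

        return json.dumps(dataclasses.asdict(self), default=enc, indent=1, sort_keys=True)


def generate_annotation(spec: SimulationSpec):
    """Random genome plus packed, non-overlapping single-exon gene models.

    Every gene is flanked by ``promoter_length`` bases kept clear of
    other gene bodies on both sides, so the strand-aware upstream window
    never truncates. Raises a sizing error naming the bp deficit when
    the genes cannot be packed into ``chrom_length``.
    """
    rng = np.random.default_rng([spec.seed, 0])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome_arr = bases[rng.integers(0, 4, size=spec.chrom_length, dtype=np.uint8)]
    genome = {"chr1": genome_arr.tobytes().decode("ascii")}

    if spec.n_genes == 0:
        annotation = pd.DataFrame(columns=mio.ANNOTATION_COLUMNS).astype(
            {"start": int, "end": int, "length": int}
        )
        return genome, annotation

    lo, hi = spec.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_genes)
    strands = rng.choice(["+", "-"], size=spec.n_genes)
    needed = int(
        lengths.sum()
        + 2 * spec.promoter_length * spec.n_genes
        + spec.intergenic_gap * (spec.n_genes - 1)
    )
    if needed > spec.chrom_length:
        raise ValueError(
            f"cannot pack {spec.n_genes} genes into {spec.chrom_length} bp: "
            f"{needed - spec.chrom_length} bp short"
        )
    rows = []
    cursor = spec.promoter_length  # 0-based; leave upstream room for gene 1
    for i in range(spec.n_genes):
        start0 = cursor
        end0 = start0 + int(lengths[i])  # half-open
        rows.append(
            (f"gene{i + 1:04d}", "chr1", start0 + 1, end0, strands[i], int(lengths[i]))
        )
        cursor = end0 + spec.promoter_length + spec.intergenic_gap + spec.promoter_length
    annotation = pd.DataFrame(rows, columns=mio.ANNOTATION_COLUMNS)
    return genome, annotation


def plant_motifs(
    genome: Mapping[str, str],
    annotation: pd.DataFrame,
    motif_spec: Sequence[MotifPlan],
    seed: int,
    promoter_length: int = 1000,
    gc_rewrite: bool = True,
) -> tuple[dict[str, str], dict[str, frozenset]]:
    """Rewrite promoters and plant exact motif instances into carriers.

    Every promoter touched by any plan is first rewritten from a GC-only
    alphabet (``gc_rewrite=True``), which makes any motif containing an
    A or T unmatchable by chance; designated carriers then receive one
    concrete expansion of the motif at a random, non-overlapping offset,
    oriented so the strand-aware promoter sequence contains it. Returns
    the modified genome and the exact carrier sets per motif id.
    """
    rng = np.random.default_rng(seed)
    contigs = {name: bytearray(seq, "ascii") for name, seq in genome.items()}
    intervals = promoter_intervals(annotation, promoter_length).set_index("gene_id")

    all_genes = list(annotation["gene_id"])
    involved: list[str] = []
    seen = set()
    for plan in motif_spec:
        for g in plan.genes if plan.genes is not None else all_genes:
            if g not in intervals.index:
                raise KeyError(f"planned gene {g!r} absent from the annotation")
            if g not in seen:
                seen.add(g)
                involved.append(g)

    def clipped(gene: str) -> tuple[bytearray, int, int]:
        row = intervals.loc[gene]
        contig = contigs[row["chrom"]]
        return contig, max(int(row["start"]), 0), min(int(row["end"]), len(contig))

    if gc_rewrite:
        for gene in involved:
            contig, s, e = clipped(gene)
            contig[s:e] = rng.choice([71, 67], size=e - s).astype(np.uint8).tobytes()

    occupied: dict[str, list[tuple[int, int]]] = {g: [] for g in involved}
    strand_of = dict(zip(annotation["gene_id"], annotation["strand"]))
    carriers: dict[str, set] = {}
    for plan in motif_spec:
        candidates = list(plan.genes) if plan.genes is not None else list(all_genes)
        if plan.n_carriers is not None:
            n_pick = plan.n_carriers
        else:
            n_pick = int(round(plan.carrier_fraction * len(candidates)))
        if n_pick > len(candidates):
            raise ValueError(
                f"{plan.motif_id}: asked for {n_pick} carriers among {len(candidates)} genes"
            )
        chosen = rng.choice(len(candidates), size=n_pick, replace=False)
        bucket = carriers.setdefault(plan.motif_id, set())
        for idx in sorted(chosen.tolist()):
            gene = candidates[idx]
            contig, s, e = clipped(gene)
            prom_len = e - s
            instance = expand_iupac(plan.iupac, rng)
            m = len(instance)
            if m > prom_len:
                raise ValueError(
                    f"motif {plan.motif_id} ({m} bp) longer than promoter of {gene} ({prom_len} bp)"
                )
            off = _free_offset(rng, occupied[gene], prom_len, m, gene, plan.motif_id)
            occupied[gene].append((off, off + m))
            if strand_of[gene] == "+":
                contig[s + off : s + off + m] = instance.encode()
            else:
                rc = instance.translate(str.maketrans("ACGT", "TGCA"))[::-1]
                contig[e - off - m : e - off] = rc.encode()
            bucket.add(gene)
    new_genome = {name: bytes(buf).decode("ascii") for name, buf in contigs.items()}
    return new_genome, {m: frozenset(g) for m, g in carriers.items()}


def _free_offset(rng, taken, prom_len, m, gene, motif_id) -> int:
    for _ in range(100):
        off = int(rng.integers(0, prom_len - m + 1))
        if all(off + m <= a or off >= b for a, b in taken):
            return off
    for off in range(prom_len - m + 1):  # dense promoter: scan exhaustively
        if all(off + m <= a or off >= b for a, b in taken):
            return off
    raise ValueError(f"no room left to plant {motif_id} in promoter of {gene}")


def generate_counts(
    annotation: pd.DataFrame, spec: SimulationSpec
) -> tuple[pd.DataFrame, GroundTruth]:
    """Negative-binomial counts with planted DE and cluster structure.

    Per-gene baseline abundances are lognormal (planted genes instead
    draw from ``planted_expr_range`` so their baseline means clear any
    expression filter); expected counts are proportional to abundance ×
    exon length and scaled per condition so column sums match the
    library sizes in expectation. Planted genes have their means
    multiplied by 2^effect in the affected conditions. Counts are
    NB(mean μ, variance μ + φμ²) with φ = ``nb_dispersion``.
    """
    rng = np.random.default_rng([spec.seed, 1])
    genes = list(annotation["gene_id"])
    n = len(genes)
    conditions = list(spec.conditions)
    control = conditions[0]

    expr = rng.lognormal(spec.expr_meanlog, spec.expr_sdlog, size=n)
    effects = np.zeros((n, len(conditions)))

    truth = GroundTruth()
    order = rng.permutation(n)
    pool = iter(order.tolist())
    plo, phi = spec.planted_expr_range

    per_comp_up: dict[str, set] = {c: set() for c in conditions[1:]}
    per_comp_down: dict[str, set] = {c: set() for c in conditions[1:]}
    for pattern in spec.de_spec:
        idx = [next(pool) for _ in range(pattern.size)]
        expr[idx] = rng.uniform(plo, phi, size=len(idx))
        for cond in pattern.conditions:
            j = conditions.index(cond)
            effects[idx, j] += pattern.signed_effect
            target = per_comp_up if pattern.direction == "up" else per_comp_down
            target[cond].update(genes[i] for i in idx)
    for label, proto in enumerate(spec.cluster_spec, start=1):
        idx = [next(pool) for _ in range(proto.size)]
        expr[idx] = rng.uniform(plo, phi, size=len(idx))
        effects[idx, :] += np.asarray(proto.log2_profile)
        for i in idx:
            truth.cluster_labels[genes[i]] = label

    lengths = annotation["length"].to_numpy(float)
    lib = spec.library_size_map()
    a = expr[:, None] * (lengths[:, None] / 1000.0) * np.exp2(effects)
    mu = a / a.sum(axis=0, keepdims=True) * np.array([lib[c] for c in conditions])

    r = 1.0 / spec.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-12)))
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=conditions)

    for cond in conditions[1:]:
        comp = f"{control}-vs-{cond}"
        truth.de_up[comp] = frozenset(per_comp_up[cond])
        truth.de_down[comp] = frozenset(per_comp_down[cond])
    truth.baseline_means = dict(zip(genes, mu[:, 0].tolist()))
    return counts_df, truth


def generate_go_map(go_spec: Sequence[GOPlan]) -> tuple[pd.DataFrame, frozenset]:
    """Flatten GO plans into a gene→term table plus the enriched truth set."""
    rows = [(g, plan.term) for plan in go_spec for g in plan.genes]
    df = pd.DataFrame(rows, columns=["gene_id", "go_id"])
    return df, frozenset(p.term for p in go_spec if p.enriched)


def random_go_spec(
    target_genes: Sequence[str],
    universe: Sequence[str],
    rng,
    enriched_terms: int = 1,
    target_fraction: float = 0.8,
    background_fraction: float = 0.05,
    n_background_terms: int = 10,
    background_term_size: int = 50,
) -> tuple[GOPlan, ...]:
    """Plant enriched terms concentrated in ``target_genes`` plus random
    background terms drawn uniformly from the universe."""
    universe = list(universe)
    target = list(target_genes)
    others = [g for g in universe if g not in set(target)]
    plans = []
    for t in range(enriched_terms):
        inside = rng.choice(target, size=max(1, int(round(target_fraction * len(target)))),
                            replace=False)
        outside = rng.choice(others, size=int(round(background_fraction * len(others))),
                             replace=False)
        plans.append(GOPlan(f"GO:E{t + 1:04d}", tuple(inside) + tuple(outside), enriched=True))
    for t in range(n_background_terms):
        members = rng.choice(universe, size=min(background_term_size, len(universe)),
                             replace=False)
        plans.append(GOPlan(f"GO:B{t + 1:04d}", tuple(members), enriched=False))
    return tuple(plans)


def generate_qpcr(
    true_log2_ratios: pd.DataFrame,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
    actin_ct: float = 20.0,
) -> pd.DataFrame:
    """Ct table whose ΔΔCt analysis recovers the given log2 ratios.

    ``true_log2_ratios`` is genes × conditions, expressed vs the control
    condition (its own column must be 0). One target and one reference
    (ACTIN1-like) Ct per replicate; Gaussian cycle noise with sd
    ``noise_sd`` on every measured Ct.
    """
    if replicates < 2:
        raise ValueError("need >= 2 replicates")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base_ct = {g: float(rng.uniform(24.0, 30.0)) for g in true_log2_ratios.index}
    rows = []
    for gene in true_log2_ratios.index:
        for cond in true_log2_ratios.columns:
            ratio = float(true_log2_ratios.loc[gene, cond])
            for rep in range(1, replicates + 1):
                rows.append(
                    (
                        gene,
                        cond,
                        rep,
                        base_ct[gene] - ratio + rng.normal(0, noise_sd) if noise_sd else base_ct[gene] - ratio,
                        actin_ct + rng.normal(0, noise_sd) if noise_sd else actin_ct,
                    )
                )
    return pd.DataFrame(rows, columns=["gene_id", "condition", "replicate", "ct_target", "ct_actin"])


def generate_gravitropism(
    group_means: Mapping[str, float],
    sd: float,
    n: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Root tip angles per seedling × treatment, normal draws clipped to
    the physically bounded [0°, 90°] range."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for treatment, mean in group_means.items():
        angles = np.clip(rng.normal(mean, sd, size=n), 0.0, 90.0)
        for i, angle in enumerate(angles, start=1):
            rows.append((f"{treatment}_s{i:03d}", treatment, float(angle)))
    return pd.DataFrame(rows, columns=["seedling_id", "treatment", "angle"])


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, plus the planted truth."""

    spec: SimulationSpec
    genome: dict[str, str]
    annotation: pd.DataFrame
    counts: pd.DataFrame
    motif_catalog: pd.DataFrame
    go_map: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        mio.write_fasta(self.genome, os.path.join(outdir, "genome.fa"))
        mio.write_gff3(self.annotation, os.path.join(outdir, "genes.gff3"))
        mio.write_counts(self.counts, os.path.join(outdir, "counts.tsv"))
        self.motif_catalog.to_csv(os.path.join(outdir, "motifs.tsv"), sep="\t", index=False)
        self.go_map.to_csv(os.path.join(outdir, "go_map.tsv"), sep="\t", index=False)
        mio.atomic_write_text(self.truth.to_json(), os.path.join(outdir, "truth.json"))


def study_dataset(
    seed: int,
    n_genes: int = 2000,
    n_up: int = 40,
    n_down: int = 16,
    log2_effect: float = 2.0,
    n_clusters: int = 8,
    cluster_size: int = 50,
    motif_query_fraction: float = 0.40,
    motif_background_fraction: float = 0.05,
) -> SyntheticDataset:
    """One synthetic study at the emulated conditions.

    Scales the real design down to a 2000-gene universe: three single
    10M-fragment libraries; planted up- and down-regulation in both
    treatments with up outnumbering down ~4.7:1 and a DEG fraction of a
    few percent, as in the study; eight co-expression prototypes; each
    catalog motif planted in 40% of the co-up genes' promoters against a
    5% genome background; one GO term enriched in the co-up set. Planted
    genes draw baseline abundance from the bulk of the background
    distribution so their baseline means clear 500 counts without
    distorting library composition.
    """
    spec = SimulationSpec(
        n_genes=n_genes,
        chrom_length=11_000_000,
        seed=seed,
        de_spec=(
            DEPattern(n_up, "up", log2_effect, ("M10", "M20")),
            DEPattern(n_down, "down", log2_effect, ("M10", "M20")),
        ),
        cluster_spec=circular_prototypes(n_clusters, size=cluster_size),
    )
    genome, annotation = generate_annotation(spec)
    counts, truth = generate_counts(annotation, spec)

    co_up = sorted(truth.de_up["M0-vs-M10"] & truth.de_up["M0-vs-M20"])
    others = tuple(g for g in annotation["gene_id"] if g not in set(co_up))
    motif_spec = []
    for motif_id, iupac in DEFAULT_MOTIFS.items():
        motif_spec.append(MotifPlan(motif_id, iupac, tuple(co_up), motif_query_fraction))
        motif_spec.append(MotifPlan(motif_id, iupac, others, motif_background_fraction))
    genome, carriers = plant_motifs(
        genome, annotation, motif_spec,
        seed=int(np.random.default_rng([seed, 2]).integers(2**31)),
        promoter_length=spec.promoter_length,
    )
    truth.motif_carriers = dict(carriers)

    go_rng = np.random.default_rng([seed, 3])
    go_spec = random_go_spec(co_up, list(annotation["gene_id"]), go_rng)
    go_map, enriched = generate_go_map(go_spec)
    truth.enriched_go = enriched

    catalog = pd.DataFrame(
        {"motif_id": list(DEFAULT_MOTIFS), "iupac": list(DEFAULT_MOTIFS.values())}
    )
    return SyntheticDataset(
        spec=spec, genome=genome, annotation=annotation, counts=counts,
        motif_catalog=catalog, go_map=go_map, truth=truth,
    )


def simulate(spec: SimulationSpec) -> SyntheticDataset:
    """Run the whole generator: annotation + genome, counts with DE and
    cluster truth, planted promoter motifs, GO map."""
    genome, annotation = generate_annotation(spec)
    counts, truth = generate_counts(annotation, spec)
    if spec.motif_spec:
        genome, carriers = plant_motifs(
            genome, annotation, spec.motif_spec,
            seed=int(np.random.default_rng([spec.seed, 2]).integers(2**31)),
            promoter_length=spec.promoter_length,
        )
        truth.motif_carriers = dict(carriers)
    go_map, enriched = generate_go_map(spec.go_spec)
    truth.enriched_go = enriched
    catalog_ids = {p.motif_id: p.iupac for p in spec.motif_spec}
    if not catalog_ids:
        catalog_ids = dict(DEFAULT_MOTIFS)
    catalog = pd.DataFrame(
        {"motif_id": list(catalog_ids), "iupac": list(catalog_ids.values())}
    )
    return SyntheticDataset(
        spec=spec,
        genome=genome,
        annotation=annotation,
        counts=counts,
        motif_catalog=catalog,
        go_map=go_map,
        truth=truth,
    )
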