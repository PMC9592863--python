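"""Synthetic three-layer expression data with planted regulatory triads.

The generator emulates post-quantification data from a two-genotype
(drought-tolerant DT, drought-sensitive DS) x two-condition (control CK,
drought) x n-replicate design: negative-binomial count matrices for the
mRNA, lncRNA, and miRNA layers, transcript annotation with genomic
coordinates, a four-tool coding-potential verdict table, miRNA-target
edges, and a :class:`PlantedTruth` record for recovery scoring.

Planted structure
-----------------
Each planted triad lives in one genotype and is either

* type 1 — miRNA up, its targeted lncRNA(s) and mRNA(s) down under
  drought, or
* type 2 — the mirror pattern;

the members' means in that genotype's drought samples are multiplied or
divided by ``2**planted_log2fc``.  Each planted (lncRNA, mRNA) pair is
realized either *cis* (placed on the same chromosome with boundary gap
<= 100 kb) or *trans* (placed apart, with counts coupled through a
Gaussian copula so their across-sample Pearson correlation exceeds the
trans-target threshold by construction).  Non-differential features share
their mean across conditions; library depths vary log-uniformly within
+/-20% so size-factor estimation is exercised.

Counts are drawn by inverse-transforming standard-normal variates through
the negative-binomial quantile function (variance mu + alpha mu^2, one
dispersion alpha shared across features), which makes the copula coupling
and plain sampling a single deterministic code path per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .lncannot import GeneModel, TranscriptRecord
from .quantify import ExpressionMatrix, SampleDesign
from .targeting import TargetEdge, edges_to_frame

#: Gaussian-copula correlation applied to planted trans pairs; together
#: with the shared condition effect this drives the across-sample Pearson
#: r of a planted pair above the 0.9 trans threshold.
TRANS_COPULA_RHO = 0.99

#: planted cis pairs are placed with a boundary gap up to this many bp
#: (strictly inside the 100 kb window)
CIS_PLACEMENT_MAX_GAP = 80_000


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the standard study
    conditions used throughout the test-suite and recovery analyses.

    ``dispersion`` is the NB overdispersion alpha (variance mu + alpha
    mu^2) shared across features.  ``planted_log2fc`` is the magnitude of
    every planted effect.  ``cis_fraction`` is the probability that a
    planted lncRNA->mRNA pair is realized by genomic proximity rather than
    by co-expression.
    """

    n_genes: int = 300
    n_lncRNAs: int = 80
    n_miRNAs: int = 40
    n_replicates: int = 3
    genotypes: tuple[str, str] = ("DT", "DS")
    baseline_mean: float = 500.0
    dispersion: float = 0.05
    n_planted_triads_per_genotype: int = 3
    planted_log2fc: float = 2.0
    frac_background_de: float = 0.05
    cis_fraction: float = 0.5
    genome_n_chromosomes: int = 3
    chromosome_length: int = 50_000_000
    seed: int = 0
    dels_per_triad: int = 1
    degs_per_triad: int = 2
    verdict_flip_rate: float = 0.0
    n_decoy_edges: int = 40

    def __post_init__(self) -> None:
        for name in (
            "n_genes", "n_lncRNAs", "n_miRNAs", "n_replicates",
            "genome_n_chromosomes", "chromosome_length",
            "dels_per_triad", "degs_per_triad",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("baseline_mean", "dispersion", "planted_log2fc"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("frac_background_de", "cis_fraction", "verdict_flip_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.n_planted_triads_per_genotype < 0:
            raise ValidationError("n_planted_triads_per_genotype must be >= 0")
        if self.n_decoy_edges < 0:
            raise ValidationError("n_decoy_edges must be >= 0")
        k = self.n_planted_triads_per_genotype * len(self.genotypes)
        if (
            k * self.dels_per_triad > self.n_lncRNAs
            or k * self.degs_per_triad > self.n_genes
            or k > self.n_miRNAs
        ):
            raise ValidationError(
                "n_planted_triads_per_genotype exceeds the available feature pools"
            )
        if len(self.genotypes) != 2 or len(set(self.genotypes)) != 2:
            raise ValidationError("genotypes must be a pair of distinct labels")


@dataclass(frozen=True)
class DEFeature:
    """One planted differential feature: where it moved and by how much."""

    feature: str
    layer: str
    genotype: str
    direction: str  # up | down, drought vs control
    log2fc: float  # signed

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValidationError(f"direction must be up/down, got {self.direction!r}")


@dataclass(frozen=True)
class PlantedTriad:
    genotype: str
    dem: str
    dels: frozenset[str]
    degs: frozenset[str]
    module_type: int  # 1: DEL down / DEM up / DEG down; 2: mirror


@dataclass(frozen=True)
class PlantedTruth:
    """The generator's record of everything planted, for recovery scoring."""

    de_features: frozenset[DEFeature]
    planted_edges: tuple[TargetEdge, ...]
    planted_triads: tuple[PlantedTriad, ...]

    def de_index(self) -> dict[tuple[str, str], DEFeature]:
        return {(d.feature, d.genotype): d for d in self.de_features}

    def validate(self) -> None:
        """Assert internal consistency of the planted structure."""
        idx = self.de_index()
        edge_keys = {(e.source, e.target, e.etype) for e in self.planted_edges}
        for tri in self.planted_triads:
            mir_dir = "up" if tri.module_type == 1 else "down"
            other_dir = "down" if tri.module_type == 1 else "up"
            dem = idx.get((tri.dem, tri.genotype))
            if dem is None or dem.direction != mir_dir:
                raise ValidationError(
                    f"triad DEM {tri.dem} missing or direction-inconsistent"
                )
            for member, layer in [(m, "lncRNA") for m in tri.dels] + [
                (m, "mRNA") for m in tri.degs
            ]:
                rec = idx.get((member, tri.genotype))
                if rec is None or rec.direction != other_dir or rec.layer != layer:
                    raise ValidationError(
                        f"triad member {member} missing or inconsistent"
                    )
            for l in tri.dels:
                if (tri.dem, l, "mir2lnc") not in edge_keys:
                    raise ValidationError(f"missing planted edge {tri.dem}->{l}")
            for g in tri.degs:
                if (tri.dem, g, "mir2mrna") not in edge_keys:
                    raise ValidationError(f"missing planted edge {tri.dem}->{g}")
            for l in tri.dels:
                for g in tri.degs:
                    if (l, g, "lnc_cis") not in edge_keys and (
                        l, g, "lnc_trans",
                    ) not in edge_keys:
                        raise ValidationError(f"missing planted pair edge {l}->{g}")


@dataclass
class SimulatedExperiment:
    """Everything one simulation run produces."""

    config: SimulationConfig
    design: SampleDesign
    counts: dict[str, ExpressionMatrix]  # keyed by layer
    transcripts: list[TranscriptRecord] = field(repr=False)
    gene_models: list[GeneModel] = field(repr=False)
    lengths: pd.Series = field(repr=False)  # spliced length per feature
    verdicts: pd.DataFrame = field(repr=False)
    edges: list[TargetEdge] = field(repr=False)
    truth: PlantedTruth = field(repr=False)
    library_factors: pd.Series = field(repr=False)
    exon_structures: dict[str, tuple[tuple[int, int], ...]] = field(
        repr=False, default_factory=dict
    )

    @property
    def annotation(self) -> pd.DataFrame:
        layer = {}
        for t in self.transcripts:
            if t.transcript_id.startswith("mir"):
                layer[t.transcript_id] = "miRNA"
            elif t.biotype == "mRNA":
                layer[t.transcript_id] = "mRNA"
            else:
                layer[t.transcript_id] = "lncRNA"
        return pd.DataFrame(
            [
                {
                    "feature": t.transcript_id,
                    "layer": layer[t.transcript_id],
                    "chrom": t.chrom,
                    "start": t.start,
                    "end": t.end,
                    "strand": t.strand,
                    "exon_count": t.exon_count,
                    "length": t.length,
                    "biotype": t.biotype,
                }
                for t in self.transcripts
            ]
        )


# ---------------------------------------------------------------------------
# structural helpers


def _make_structure(
    rng: np.random.Generator,
    n: int,
    exon_len: tuple[int, int],
    intron_len: tuple[int, int],
    exon_range: tuple[int, int],
    n_chrom: int,
    chrom_len: int,
    prefix: str,
) -> list[tuple[str, str, int, str, list[tuple[int, int]]]]:
    """Lay out n multi-exon transcripts: (id, chrom, start, strand, exons)."""
    out = []
    for i in range(n):
        k = int(rng.integers(exon_range[0], exon_range[1] + 1))
        ex_lens = rng.integers(exon_len[0], exon_len[1] + 1, size=k)
        in_lens = rng.integers(intron_len[0], intron_len[1] + 1, size=k - 1)
        span = int(ex_lens.sum() + in_lens.sum())
        chrom = f"chr{int(rng.integers(1, n_chrom + 1))}"
        start = int(rng.integers(1, chrom_len - span))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = start
        for j in range(k):
            exons.append((pos, pos + int(ex_lens[j]) - 1))
            pos += int(ex_lens[j])
            if j < k - 1:
                pos += int(in_lens[j])
        out.append((f"{prefix}{i + 1:04d}", chrom, start, strand, exons))
    return out


def _shift_exons(exons: list[tuple[int, int]], new_start: int) -> list[tuple[int, int]]:
    delta = new_start - exons[0][0]
    return [(s + delta, e + delta) for s, e in exons]


def _nb_ppf(q: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB quantile with variance mu + alpha mu^2 (scipy n/p convention)."""
    r = 1.0 / alpha
    p = r / (r + mu)
    return stats.nbinom.ppf(q, r, p)


# ---------------------------------------------------------------------------
# the generator


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate one full synthetic experiment; bit-identical per seed."""
    rng = np.random.default_rng(config.seed)
    g1, g2 = config.genotypes

    # --- sample design -----------------------------------------------------
    rows = []
    for g in config.genotypes:
        for cond, tag in (("CK", "CK"), ("drought", "T")):
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {"sample": f"{g}{tag}{rep}", "genotype": g,
                     "condition": cond, "replicate": rep}
                )
    design = SampleDesign(pd.DataFrame(rows))
    samples = design.samples

    # --- genomic structure -------------------------------------------------
    genes = _make_structure(
        rng, config.n_genes, (150, 1500), (100, 2000), (2, 6),
        config.genome_n_chromosomes, config.chromosome_length, "gene",
    )
    lncs = _make_structure(
        rng, config.n_lncRNAs, (150, 600), (60, 500), (2, 4),
        config.genome_n_chromosomes, config.chromosome_length, "lnc",
    )
    mirs = []
    for i in range(config.n_miRNAs):
        length = int(rng.integers(20, 25))
        chrom = f"chr{int(rng.integers(1, config.genome_n_chromosomes + 1))}"
        start = int(rng.integers(1, config.chromosome_length - length))
        strand = "+" if rng.random() < 0.5 else "-"
        mirs.append((f"mir{i + 1:04d}", chrom, start, strand,
                     [(start, start + length - 1)]))

    gene_ids = [g[0] for g in genes]
    lnc_ids = [l[0] for l in lncs]
    mir_ids = [m[0] for m in mirs]

    # --- choose planted members (disjoint pools across genotypes) ----------
    n_tri = config.n_planted_triads_per_genotype
    mir_pool = list(rng.permutation(mir_ids))
    lnc_pool = list(rng.permutation(lnc_ids))
    gene_pool = list(rng.permutation(gene_ids))

    triads: list[PlantedTriad] = []
    de_features: list[DEFeature] = []
    planted_edges: list[TargetEdge] = []
    effects: dict[str, tuple[str, float]] = {}  # feature -> (genotype, signed lfc)
    trans_pairs: list[tuple[str, str]] = []  # (lnc, gene) copula-coupled
    cis_pairs: list[tuple[str, str]] = []

    lfc = config.planted_log2fc
    for g in config.genotypes:
        for t in range(n_tri):
            module_type = 1 if t % 2 == 0 else 2
            mir_dir = "up" if module_type == 1 else "down"
            other_dir = "down" if module_type == 1 else "up"
            mir_sign = 1.0 if module_type == 1 else -1.0
            dem = mir_pool.pop()
            dels = frozenset(lnc_pool.pop() for _ in range(config.dels_per_triad))
            degs = frozenset(gene_pool.pop() for _ in range(config.degs_per_triad))
            triads.append(PlantedTriad(g, dem, dels, degs, module_type))
            effects[dem] = (g, mir_sign * lfc)
            de_features.append(DEFeature(dem, "miRNA", g, mir_dir, mir_sign * lfc))
            for l in sorted(dels):
                effects[l] = (g, -mir_sign * lfc)
                de_features.append(DEFeature(l, "lncRNA", g, other_dir, -mir_sign * lfc))
                planted_edges.append(TargetEdge(dem, l, "mir2lnc"))
            for d in sorted(degs):
                effects[d] = (g, -mir_sign * lfc)
                de_features.append(DEFeature(d, "mRNA", g, other_dir, -mir_sign * lfc))
                planted_edges.append(TargetEdge(dem, d, "mir2mrna"))
            for l in sorted(dels):
                for d in sorted(degs):
                    if rng.random() < config.cis_fraction:
                        cis_pairs.append((l, d))
                    else:
                        trans_pairs.append((l, d))

    # --- background DE -----------------------------------------------------
    for layer, ids in (("mRNA", gene_ids), ("lncRNA", lnc_ids), ("miRNA", mir_ids)):
        for f in ids:
            if f in effects:
                continue
            if rng.random() < config.frac_background_de:
                g = config.genotypes[int(rng.integers(0, 2))]
                sign = 1.0 if rng.random() < 0.5 else -1.0
                effects[f] = (g, sign * lfc)
                de_features.append(
                    DEFeature(f, layer, g, "up" if sign > 0 else "down", sign * lfc)
                )

    # --- realize cis / trans placements ------------------------------------
    lnc_by_id = {l[0]: l for l in lncs}
    gene_by_id = {g[0]: g for g in genes}

    def _span(exons: list[tuple[int, int]]) -> int:
        return exons[-1][1] - exons[0][0] + 1

    cis_relocated: set[str] = set()
    for l_id, g_id in cis_pairs:
        _, l_chrom, _, _, l_exons = lnc_by_id[l_id]
        gid, _, _, g_strand, g_exons = gene_by_id[g_id]
        gap = int(rng.integers(0, CIS_PLACEMENT_MAX_GAP + 1))
        new_start = l_exons[-1][1] + gap + 1
        if new_start + _span(g_exons) >= config.chromosome_length:
            # fall back to the upstream side near the chromosome end
            new_start = max(1, l_exons[0][0] - gap - _span(g_exons))
        gene_by_id[g_id] = (gid, l_chrom, new_start, g_strand,
                           _shift_exons(g_exons, new_start))
        cis_relocated.add(g_id)

    for l_id, g_id in trans_pairs:
        if g_id in cis_relocated:
            # already pinned near another planted lncRNA; the copula link
            # below still realizes the trans co-expression
            continue
        _, l_chrom, _, _, l_exons = lnc_by_id[l_id]
        gid, g_chrom, g_start, g_strand, g_exons = gene_by_id[g_id]
        # re-place until clearly outside the cis window of the partner
        tries = 0
        while True:
            far = (
                g_chrom != l_chrom
                or min(
                    abs(g_exons[0][0] - l_exons[-1][1]),
                    abs(l_exons[0][0] - g_exons[-1][1]),
                ) - 1 > 100_000 + CIS_PLACEMENT_MAX_GAP
            )
            if far or tries > 50:
                break
            g_chrom = f"chr{int(rng.integers(1, config.genome_n_chromosomes + 1))}"
            g_start = int(rng.integers(1, config.chromosome_length - _span(g_exons)))
            g_exons = _shift_exons(g_exons, g_start)
            tries += 1
        gene_by_id[g_id] = (gid, g_chrom, g_start, g_strand, g_exons)

    genes = [gene_by_id[g] for g in gene_ids]

    # planted pair edges recorded in truth
    for l_id, g_id in cis_pairs:
        _, _, _, _, l_exons = lnc_by_id[l_id]
        _, _, _, _, g_exons = gene_by_id[g_id]
        a = (l_exons[0][0], l_exons[-1][1])
        b = (g_exons[0][0], g_exons[-1][1])
        d = 0 if a[0] <= b[1] and b[0] <= a[1] else max(a[0], b[0]) - min(a[1], b[1]) - 1
        planted_edges.append(TargetEdge(l_id, g_id, "lnc_cis", distance=int(d)))
    for l_id, g_id in trans_pairs:
        planted_edges.append(TargetEdge(l_id, g_id, "lnc_trans"))

    # --- decoy miRNA edges (not part of any triad) --------------------------
    edges: list[TargetEdge] = [
        e for e in planted_edges if e.etype in ("mir2lnc", "mir2mrna")
    ]
    seen = {(e.source, e.target, e.etype) for e in edges}
    for etype, pool in (("mir2lnc", lnc_ids), ("mir2mrna", gene_ids)):
        made = 0
        while made < config.n_decoy_edges:
            src = mir_ids[int(rng.integers(0, len(mir_ids)))]
            tgt = pool[int(rng.integers(0, len(pool)))]
            if (src, tgt, etype) in seen:
                continue
            seen.add((src, tgt, etype))
            edges.append(TargetEdge(src, tgt, etype))
            made += 1

    # --- expression means ---------------------------------------------------
    lib = np.exp(rng.uniform(np.log(0.8), np.log(1.2), size=len(samples)))
    library_factors = pd.Series(lib, index=samples, name="library_factor")
    drought_mask = {
        g: np.array(
            [
                (row["genotype"] == g and row["condition"] == "drought")
                for _, row in design.table.iterrows()
            ]
        )
        for g in config.genotypes
    }

    def _mu(ids: list[str]) -> np.ndarray:
        mu = np.full((len(ids), len(samples)), config.baseline_mean)
        for i, f in enumerate(ids):
            if f in effects:
                g, delta = effects[f]
                mu[i, drought_mask[g]] *= 2.0 ** delta
        return mu * lib[None, :]

    # --- counts via Gaussian copula -> NB quantiles -------------------------
    z_gene = rng.standard_normal((len(gene_ids), len(samples)))
    z_lnc = rng.standard_normal((len(lnc_ids), len(samples)))
    z_mir = rng.standard_normal((len(mir_ids), len(samples)))
    lnc_index = {f: i for i, f in enumerate(lnc_ids)}
    gene_index = {f: i for i, f in enumerate(gene_ids)}
    rho = TRANS_COPULA_RHO
    for l_id, g_id in trans_pairs:
        i, j = lnc_index[l_id], gene_index[g_id]
        z_gene[j] = rho * z_lnc[i] + np.sqrt(1 - rho**2) * z_gene[j]

    counts = {}
    for layer, ids, z in (
        ("mRNA", gene_ids, z_gene),
        ("lncRNA", lnc_ids, z_lnc),
        ("miRNA", mir_ids, z_mir),
    ):
        q = stats.norm.cdf(z)
        mat = _nb_ppf(q, _mu(ids), config.dispersion).astype(int)
        counts[layer] = ExpressionMatrix(
            values=pd.DataFrame(mat, index=ids, columns=samples),
            unit="counts",
            design=design,
        )

    # --- transcript records, gene models, verdicts --------------------------
    transcripts: list[TranscriptRecord] = []
    gene_models: list[GeneModel] = []
    lengths = {}
    for gid, chrom, start, strand, exons in genes:
        length = sum(e - s + 1 for s, e in exons)
        lengths[gid] = length
        transcripts.append(
            TranscriptRecord(gid, chrom, exons[0][0], exons[-1][1], strand,
                             len(exons), length, biotype="mRNA")
        )
        gene_models.append(
            GeneModel(gid, chrom, exons[0][0], exons[-1][1], strand, tuple(exons))
        )
    for lid, chrom, start, strand, exons in lncs:
        length = sum(e - s + 1 for s, e in exons)
        lengths[lid] = length
        transcripts.append(
            TranscriptRecord(lid, chrom, exons[0][0], exons[-1][1], strand,
                             len(exons), length, biotype="unknown")
        )
    for mid, chrom, start, strand, exons in mirs:
        length = exons[0][1] - exons[0][0] + 1
        lengths[mid] = length
        transcripts.append(
            TranscriptRecord(mid, chrom, exons[0][0], exons[0][1], strand,
                             1, length, biotype="unknown")
        )

    flip = rng.random((len(gene_ids) + len(lnc_ids), 4)) < config.verdict_flip_rate
    verdict_rows = []
    for i, f in enumerate(gene_ids + lnc_ids):
        noncoding = f.startswith("lnc")
        row = {"transcript": f}
        for j, tool in enumerate(("cpc", "cnci", "cpat", "pfam")):
            row[tool] = int(noncoding != bool(flip[i, j]))
        verdict_rows.append(row)
    verdicts = pd.DataFrame(verdict_rows).set_index("transcript")

    truth = PlantedTruth(
        de_features=frozenset(de_features),
        planted_edges=tuple(planted_edges),
        planted_triads=tuple(triads),
    )
    truth.validate()

    exon_structures = {
        fid: tuple(exons) for fid, _, _, _, exons in genes + lncs + mirs
    }

    return SimulatedExperiment(
        config=config,
        design=design,
        counts=counts,
        transcripts=transcripts,
        gene_models=gene_models,
        lengths=pd.Series(lengths, name="length"),
        verdicts=verdicts,
        edges=edges,
        truth=truth,
        library_factors=library_factors,
        exon_structures=exon_structures,
    )


# ---------------------------------------------------------------------------
# writers


def write_gtf(sim: SimulatedExperiment, path: str | Path) -> None:
    """Write transcripts and exons as GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for t in sim.transcripts:
            attrs = f'gene_id "{t.transcript_id}_g"; transcript_id "{t.transcript_id}";'
            if t.biotype == "mRNA":
                attrs += ' transcript_biotype "mRNA";'
            fh.write(
                f"{t.chrom}\ttriadscreen\ttranscript\t{t.start}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            exons = sim.exon_structures.get(
                t.transcript_id, ((t.start, t.end),)
            )
            for s, e in exons:
                fh.write(
                    f"{t.chrom}\ttriadscreen\texon\t{s}\t{e}\t.\t{t.strand}\t.\t"
                    f"{attrs}\n"
                )


def write_experiment(sim: SimulatedExperiment, outdir: str | Path) -> None:
    """Write all generator outputs as plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for layer, em in sim.counts.items():
        em.to_tsv(out / f"counts_{layer}.tsv")
    sim.design.to_tsv(out / "design.tsv")
    sim.annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
    write_gtf(sim, out / "annotation.gtf")
    sim.verdicts.reset_index().to_csv(out / "verdicts.tsv", sep="\t", index=False)
    edges_to_frame(sim.edges).to_csv(out / "edges.tsv", sep="\t", index=False)
    truth = {
        "de_features": [asdict(d) for d in sorted(
            sim.truth.de_features, key=lambda d: (d.layer, d.feature, d.genotype)
        )],
        "planted_edges": [
            {"source": e.source, "target": e.target, "type": e.etype,
             "distance": e.distance}
            for e in sim.truth.planted_edges
        ],
        "planted_triads": [
            {"genotype": t.genotype, "dem": t.dem, "dels": sorted(t.dels),
             "degs": sorted(t.degs), "module_type": t.module_type}
            for t in sim.truth.planted_triads
        ],
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
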