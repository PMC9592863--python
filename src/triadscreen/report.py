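"""Pipeline driver, summary tables, recovery scoring, and qPCR arithmetic.

``run_pipeline`` chains the stages in method order — simulate (or load),
normalize, test differential expression per layer and genotype, filter and
classify lncRNAs, build the cis/trans/miRNA edge layers, run the
drought-resistance DEG classifier and the triad module screen — and
collects one summary dictionary whose granularity mirrors study-level
reporting: per-layer per-genotype up/down tallies, two-genotype overlap
quadruples, drought-class counts, and the emitted modules.  When the input
is simulated, recovery of the planted truth (DE sensitivity and false-call
rate, module precision/recall) is scored as well.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import diffexpr, lncannot, quantify, screens, synthdata, targeting
from .exceptions import ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# qPCR relative quantification


def ddct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Comparative 2^-ddCt relative expression fold.

    dCt = Ct_target - Ct_reference within each state; ddCt is the treated
    dCt minus the control dCt; the fold change of the target, relative to
    the reference gene and the control state, is 2^-ddCt.  Ct values must
    lie in the open interval (0, 50) cycles.
    """
    cts = {
        "ct_target_treated": ct_target_treated,
        "ct_ref_treated": ct_ref_treated,
        "ct_target_control": ct_target_control,
        "ct_ref_control": ct_ref_control,
    }
    for name, v in cts.items():
        if not 0 < v < 50:
            raise ValidationError(f"{name}={v} outside the valid Ct range (0, 50)")
    ddct_value = (ct_target_treated - ct_ref_treated) - (
        ct_target_control - ct_ref_control
    )
    return 2.0 ** (-ddct_value)


# ---------------------------------------------------------------------------
# recovery scoring against planted truth


@dataclass(frozen=True)
class DERecovery:
    sensitivity: float
    false_call_rate: float
    n_planted: int
    n_recovered: int
    n_null: int
    n_false: int


def score_de_recovery(
    truth: synthdata.PlantedTruth,
    results: dict[tuple[str, str], pd.DataFrame],
) -> DERecovery:
    """Score DE calls against the planted truth.

    ``results`` maps (layer, genotype) to that contrast's differential
    table (with a ``direction`` column).  Sensitivity counts a planted
    feature as recovered when it is called in the planted direction in the
    planted genotype; the false-call rate is the fraction of
    feature-by-genotype nulls that were called anyway.
    """
    planted = {(d.feature, d.genotype): d.direction for d in truth.de_features}
    n_planted = n_recovered = n_null = n_false = 0
    for (layer, genotype), df in results.items():
        for feat, direction in zip(df["feature"], df["direction"]):
            key = (feat, genotype)
            if key in planted:
                n_planted += 1
                if direction == planted[key]:
                    n_recovered += 1
            else:
                n_null += 1
                if direction != "none":
                    n_false += 1
    return DERecovery(
        sensitivity=n_recovered / n_planted if n_planted else float("nan"),
        false_call_rate=n_false / n_null if n_null else float("nan"),
        n_planted=n_planted,
        n_recovered=n_recovered,
        n_null=n_null,
        n_false=n_false,
    )


@dataclass(frozen=True)
class ModuleRecovery:
    precision: float
    recall: float
    n_planted: int
    n_emitted: int
    n_matched: int


def score_module_recovery(
    truth: synthdata.PlantedTruth, modules: list[screens.TriadModule]
) -> ModuleRecovery:
    """Module-level precision/recall against the planted triads.

    A planted triad is recovered when an emitted module shares its
    genotype, DEM, and type and contains all planted DEL/DEG members; an
    emitted module is a true positive when its (genotype, DEM, type)
    matches a planted triad.
    """
    planted = {(t.genotype, t.dem, t.module_type): t for t in truth.planted_triads}
    emitted = {(m.genotype, m.dem, m.module_type): m for m in modules}
    n_matched = sum(1 for k in emitted if k in planted)
    n_recalled = sum(
        1
        for k, t in planted.items()
        if k in emitted
        and t.dels <= emitted[k].dels
        and t.degs <= emitted[k].degs
    )
    return ModuleRecovery(
        precision=n_matched / len(emitted) if emitted else float("nan"),
        recall=n_recalled / len(planted) if planted else float("nan"),
        n_planted=len(planted),
        n_emitted=len(modules),
        n_matched=n_matched,
    )


# ---------------------------------------------------------------------------
# the pipeline driver


@dataclass
class PipelineResult:
    sim: synthdata.SimulatedExperiment
    de_results: dict[tuple[str, str], pd.DataFrame] = field(repr=False)
    accepted_lncs: set[str] = field(repr=False)
    lnc_classes: pd.DataFrame = field(repr=False)
    edges: list[targeting.TargetEdge] = field(repr=False)
    drought_classes: pd.DataFrame = field(repr=False)
    modules: list[screens.TriadModule] = field(repr=False)
    summary: dict = field(repr=False)


def _tally(df: pd.DataFrame) -> dict:
    up = int((df["direction"] == "up").sum())
    down = int((df["direction"] == "down").sum())
    return {"up": up, "down": down, "total": up + down}


def run_pipeline(
    sim_config: synthdata.SimulationConfig | None = None,
    thresholds: diffexpr.ThresholdConfig | None = None,
    sim: synthdata.SimulatedExperiment | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full screen on a simulated experiment.

    Either pass a ready :class:`SimulatedExperiment` via ``sim`` or a
    :class:`SimulationConfig` (``sim_config``); thresholds default to the
    standard study values.  Deterministic given the simulation seed.
    """
    thresholds = thresholds or diffexpr.ThresholdConfig()
    if sim is None:
        sim_config = sim_config or synthdata.SimulationConfig()
        sim = synthdata.simulate_experiment(sim_config)
    cfg = sim.config
    logger.info("pipeline: %d genes, %d lncRNAs, %d miRNAs, %d samples",
                cfg.n_genes, cfg.n_lncRNAs, cfg.n_miRNAs,
                len(sim.design.samples))

    # --- lncRNA filtering and classification --------------------------------
    lnc_records = [t for t in sim.transcripts
                   if t.biotype == "unknown" and t.transcript_id.startswith("lnc")]
    accepted = lncannot.consensus_filter(lnc_records, sim.verdicts, thresholds)
    accepted_records = [t for t in lnc_records if t.transcript_id in accepted]
    lnc_classes = lncannot.classify_all(accepted_records, sim.gene_models)
    logger.info("lncRNA filter: %d candidates -> %d accepted",
                len(lnc_records), len(accepted))

    # --- miRNA length filter -------------------------------------------------
    mir_lengths = sim.lengths[sim.counts["miRNA"].features]
    mir_keep = [
        f for f, L in mir_lengths.items()
        if thresholds.mirna_len_min <= L <= thresholds.mirna_len_max
    ]
    logger.info("miRNA length filter: %d -> %d", len(mir_lengths), len(mir_keep))

    counts = {
        "mRNA": sim.counts["mRNA"],
        "lncRNA": sim.counts["lncRNA"].subset_features(sorted(accepted)),
        "miRNA": sim.counts["miRNA"].subset_features(mir_keep),
    }

    # --- differential expression ---------------------------------------------
    de_results: dict[tuple[str, str], pd.DataFrame] = {}
    for layer in ("mRNA", "lncRNA", "miRNA"):
        for genotype in cfg.genotypes:
            de_results[(layer, genotype)] = diffexpr.nb_test(
                counts[layer], genotype, thresholds, layer=layer
            )

    # --- normalized abundances for the trans correlation ----------------------
    gene_fpkm = quantify.fpkm(counts["mRNA"], sim.lengths)
    lnc_fpkm = quantify.fpkm(counts["lncRNA"], sim.lengths)

    # --- edge layers -----------------------------------------------------------
    gene_records = [t for t in sim.transcripts if t.biotype == "mRNA"]
    cis = targeting.cis_targets(accepted_records, gene_records, thresholds)
    trans = targeting.trans_targets(lnc_fpkm, gene_fpkm, thresholds)
    mir_edges = [e for e in sim.edges if e.etype in ("mir2lnc", "mir2mrna")]
    edges = mir_edges + cis + trans
    logger.info("edges: %d cis, %d trans, %d miRNA", len(cis), len(trans),
                len(mir_edges))

    # --- screens ---------------------------------------------------------------
    g_dt, g_ds = ("DT", "DS") if set(cfg.genotypes) == {"DT", "DS"} else cfg.genotypes
    drought_classes = screens.classify_drought_degs(
        de_results[("mRNA", g_ds)], de_results[("mRNA", g_dt)], thresholds
    )
    modules: list[screens.TriadModule] = []
    for genotype in cfg.genotypes:
        modules.extend(
            screens.screen_triads(
                {layer: de_results[(layer, genotype)] for layer in
                 ("mRNA", "lncRNA", "miRNA")},
                edges,
                genotype,
                thresholds,
            )
        )

    # --- summary ----------------------------------------------------------------
    summary: dict = {"layers": {}, "venn": {}, "lncRNA_filter": {
        "candidates": len(lnc_records), "accepted": len(accepted),
        "classes": lnc_classes["lnc_class"].value_counts().to_dict(),
    }}
    for layer in ("mRNA", "lncRNA", "miRNA"):
        per_geno = {}
        for genotype in cfg.genotypes:
            per_geno[genotype] = _tally(de_results[(layer, genotype)])
        summary["layers"][layer] = per_geno
        cs = diffexpr.call_sets(
            de_results[(layer, g_ds)], de_results[(layer, g_dt)], thresholds
        )
        v = diffexpr.venn(cs.ds, cs.dt)
        summary["venn"][layer] = {
            "common": v.common, "ds_specific": v.ds_specific,
            "dt_specific": v.dt_specific, "union": v.union,
        }
    summary["drought_classes"] = {
        c: int((drought_classes["drought_class"] == c).sum())
        for c in screens.DROUGHT_CLASSES
    }
    summary["modules"] = [m.to_dict() for m in modules]
    summary["n_modules"] = len(modules)

    de_rec = score_de_recovery(sim.truth, de_results)
    mod_rec = score_module_recovery(sim.truth, modules)
    summary["recovery"] = {
        "de_sensitivity": de_rec.sensitivity,
        "de_false_call_rate": de_rec.false_call_rate,
        "module_precision": mod_rec.precision,
        "module_recall": mod_rec.recall,
        "n_planted_triads": mod_rec.n_planted,
        "n_emitted_modules": mod_rec.n_emitted,
    }

    result = PipelineResult(
        sim=sim,
        de_results=de_results,
        accepted_lncs=accepted,
        lnc_classes=lnc_classes,
        edges=edges,
        drought_classes=drought_classes,
        modules=modules,
        summary=summary,
    )
    if outdir is not None:
        write_results(result, outdir)
    return result


def write_results(result: PipelineResult, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    synthdata.write_experiment(result.sim, out / "inputs")
    for (layer, genotype), df in result.de_results.items():
        df.to_csv(out / f"de_{layer}_{genotype}.tsv", sep="\t", index=False)
    result.lnc_classes.to_csv(out / "lnc_classes.tsv", sep="\t", index=False)
    targeting.write_edges_tsv(result.edges, out / "edges_computed.tsv")
    result.drought_classes.to_csv(out / "drought_classes.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(json.dumps(result.summary, indent=1))
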