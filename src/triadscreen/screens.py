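"""The two study-level screens.

1. **Drought-resistance DEG classifier** — partitions differentially
   expressed genes into six mutually exclusive classes from the DS and DT
   contrast results:

   * A/B: DT-specific response — called in DT only, with |log2FC(DT)| > 2
     (A up, B down);
   * C/D: shared but amplified response — called in both genotypes with the
     same sign and log2FC(DT)/log2FC(DS) > 3 (C up, D down);
   * E/F: opposite response — called in both genotypes with opposite signs
     (E: DS down / DT up, F: DS up / DT down).

2. **Triad (ceRNA) module screen** — for each differentially expressed
   miRNA (DEM), collects its targeted differentially expressed lncRNAs
   (DELs) and genes (DEGs) whose expression moved in the opposite
   direction, then retains only DEL/DEG members participating in at least
   one (DEL, DEG) pair that itself carries a cis or trans targeting
   relation.  A DEM with non-empty retained DEL and DEG sets yields one
   module: type 1 = DEL down / DEM up / DEG down, type 2 = the mirror
   pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .diffexpr import ThresholdConfig, _assign_directions
from .exceptions import ValidationError
from .targeting import TargetEdge

logger = logging.getLogger(__name__)

DROUGHT_CLASSES = ("A", "B", "C", "D", "E", "F", "none")

_OPPOSITE = {"up": "down", "down": "up"}


def classify_drought_degs(
    ds_results: pd.DataFrame,
    dt_results: pd.DataFrame,
    config: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Assign each feature one drought-resistance class (or ``none``).

    Features present in only one genotype's results are treated as not
    called in the other (logged).  Returns columns
    ``feature, drought_class, log2fc_ds, log2fc_dt``.
    """
    config = config or ThresholdConfig()
    ds = _assign_directions(ds_results, config).set_index("feature")
    dt = _assign_directions(dt_results, config).set_index("feature")
    only = set(ds.index) ^ set(dt.index)
    if only:
        logger.info(
            "%d features present in one genotype's results only; "
            "treated as not called there", len(only),
        )
    rows = []
    for feat in sorted(set(ds.index) | set(dt.index)):
        in_ds, in_dt = feat in ds.index, feat in dt.index
        dir_ds = ds.at[feat, "direction"] if in_ds else "none"
        dir_dt = dt.at[feat, "direction"] if in_dt else "none"
        lfc_ds = float(ds.at[feat, "log2fc"]) if in_ds else float("nan")
        lfc_dt = float(dt.at[feat, "log2fc"]) if in_dt else float("nan")
        called_ds, called_dt = dir_ds != "none", dir_dt != "none"
        cls = "none"
        if called_dt and not called_ds and abs(lfc_dt) > config.dt_specific_lfc:
            cls = "A" if lfc_dt > 0 else "B"
        elif called_ds and called_dt:
            if dir_ds == dir_dt:
                if lfc_dt / lfc_ds > config.lfc_ratio:
                    cls = "C" if lfc_dt > 0 else "D"
            else:
                cls = "E" if dir_ds == "down" else "F"
        rows.append(
            {"feature": feat, "drought_class": cls,
             "log2fc_ds": lfc_ds, "log2fc_dt": lfc_dt}
        )
    return pd.DataFrame(rows, columns=["feature", "drought_class",
                                       "log2fc_ds", "log2fc_dt"])


@dataclass(frozen=True)
class TriadModule:
    """A DEM-centered regulatory module.

    ``module_type`` 1 means DEL down / DEM up / DEG down; 2 the mirror.
    ``edges`` holds the supporting TargetEdge evidence.
    """

    genotype: str
    dem: str
    dels: frozenset[str]
    degs: frozenset[str]
    module_type: int
    edges: tuple[TargetEdge, ...] = ()

    def __post_init__(self) -> None:
        if self.module_type not in (1, 2):
            raise ValidationError(f"module type must be 1 or 2, got {self.module_type}")
        if not self.dels or not self.degs:
            raise ValidationError("a module needs non-empty DEL and DEG sets")

    def to_dict(self) -> dict:
        return {
            "genotype": self.genotype,
            "dem": self.dem,
            "dels": sorted(self.dels),
            "degs": sorted(self.degs),
            "module_type": self.module_type,
            "edges": [
                {"source": e.source, "target": e.target, "type": e.etype}
                for e in self.edges
            ],
        }


def _directions(results: pd.DataFrame, config: ThresholdConfig) -> dict[str, str]:
    d = _assign_directions(results, config)
    return dict(zip(d["feature"], d["direction"]))


def screen_triads(
    de_by_layer: dict[str, pd.DataFrame],
    edges: list[TargetEdge],
    genotype: str,
    config: ThresholdConfig | None = None,
    require_pair_link: bool = True,
) -> list[TriadModule]:
    """Direction-constrained DEL-DEM-DEG module screen for one genotype.

    Parameters
    ----------
    de_by_layer:
        Mapping with keys ``mRNA``, ``lncRNA``, ``miRNA`` to that layer's
        differential results for this genotype.
    edges:
        The combined edge table (mir2lnc, mir2mrna, lnc_cis, lnc_trans).
        Edges naming features absent from the results are ignored.
    require_pair_link:
        When True (default) each retained DEL/DEG must participate in at
        least one (DEL, DEG) pair joined by a cis or trans edge; when False
        the DEM's opposite-direction targets are kept as long as at least
        one linked (DEL, DEG) pair exists in the module.
    """
    config = config or ThresholdConfig()
    for layer in ("mRNA", "lncRNA", "miRNA"):
        if layer not in de_by_layer:
            raise ValidationError(f"missing differential results for layer {layer!r}")
    gene_dir = _directions(de_by_layer["mRNA"], config)
    lnc_dir = _directions(de_by_layer["lncRNA"], config)
    mir_dir = _directions(de_by_layer["miRNA"], config)

    mir2lnc: dict[str, set[str]] = {}
    mir2gene: dict[str, set[str]] = {}
    lnc2gene: dict[str, set[str]] = {}
    edge_index: dict[tuple[str, str, str], TargetEdge] = {}
    for e in edges:
        edge_index.setdefault((e.source, e.target, e.etype), e)
        if e.etype == "mir2lnc":
            mir2lnc.setdefault(e.source, set()).add(e.target)
        elif e.etype == "mir2mrna":
            mir2gene.setdefault(e.source, set()).add(e.target)
        else:  # lnc_cis / lnc_trans
            lnc2gene.setdefault(e.source, set()).add(e.target)

    modules: list[TriadModule] = []
    for dem in sorted(mir_dir):
        d = mir_dir[dem]
        if d == "none":
            continue
        opp = _OPPOSITE[d]
        cand_dels = {t for t in mir2lnc.get(dem, ()) if lnc_dir.get(t) == opp}
        cand_degs = {t for t in mir2gene.get(dem, ()) if gene_dir.get(t) == opp}
        if not cand_dels or not cand_degs:
            continue
        pairs = {
            (l, g)
            for l in cand_dels
            for g in lnc2gene.get(l, ())
            if g in cand_degs
        }
        if require_pair_link:
            dels = {l for l, _ in pairs}
            degs = {g for _, g in pairs}
        else:
            dels, degs = (cand_dels, cand_degs) if pairs else (set(), set())
        if not dels or not degs:
            continue
        evidence: list[TargetEdge] = []
        for l in sorted(dels):
            evidence.append(edge_index[(dem, l, "mir2lnc")])
        for g in sorted(degs):
            evidence.append(edge_index[(dem, g, "mir2mrna")])
        for l, g in sorted(pairs):
            for et in ("lnc_cis", "lnc_trans"):
                if (l, g, et) in edge_index:
                    evidence.append(edge_index[(l, g, et)])
        module = TriadModule(
            genotype=genotype,
            dem=dem,
            dels=frozenset(dels),
            degs=frozenset(degs),
            module_type=1 if d == "up" else 2,
            edges=tuple(evidence),
        )
        _check_module(module, mir_dir, lnc_dir, gene_dir, lnc2gene,
                      mir2lnc, mir2gene, require_pair_link)
        modules.append(module)
    return modules


def _check_module(
    m: TriadModule,
    mir_dir: dict[str, str],
    lnc_dir: dict[str, str],
    gene_dir: dict[str, str],
    lnc2gene: dict[str, set[str]],
    mir2lnc: dict[str, set[str]],
    mir2gene: dict[str, set[str]],
    require_pair_link: bool,
) -> None:
    """Runtime assertion of the module invariants on every emitted module."""
    d = mir_dir[m.dem]
    opp = _OPPOSITE[d]
    assert m.module_type == (1 if d == "up" else 2)
    for l in m.dels:
        assert l in mir2lnc.get(m.dem, set()), "DEL lacks a mir2lnc edge"
        assert lnc_dir.get(l) == opp, "DEL direction inconsistent with module type"
    for g in m.degs:
        assert g in mir2gene.get(m.dem, set()), "DEG lacks a mir2mrna edge"
        assert gene_dir.get(g) == opp, "DEG direction inconsistent with module type"
    if require_pair_link:
        for l in m.dels:
            assert lnc2gene.get(l, set()) & m.degs, "retained DEL has no linked DEG"
        for g in m.degs:
            assert any(g in lnc2gene.get(l, set()) for l in m.dels), \
                "retained DEG has no linked DEL"
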