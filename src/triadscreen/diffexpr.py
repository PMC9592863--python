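"""Per-genotype drought-vs-control differential expression and set summaries.

Each RNA layer is tested genotype by genotype with a transparent
negative-binomial Wald test: counts are scaled by median-of-ratios size
factors, per-feature dispersion is estimated by the method of moments with a
non-negativity floor, and the log2 fold change (drought over control, with a
pseudocount) is referred to a t distribution with n1 + n2 - 2 degrees of
freedom.  The t reference, rather than a normal one, absorbs the noise of
moment-based dispersion estimates at typical replicate counts (n = 3 per
condition) and keeps the type-I error at its nominal level.

A feature is *called* differentially expressed when p < ``de_p`` and
|log2FC| > ``de_lfc`` (strict inequalities; defaults 0.05 and 1).
``call_sets`` and ``venn`` provide the per-genotype up/down id sets and the
two-set overlap arithmetic used in study-level summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .quantify import ExpressionMatrix, size_factors

_LN2 = math.log(2.0)

#: dispersion floor: the NB variance never drops below the Poisson variance
DISPERSION_FLOOR = 1e-8
#: pseudocount (in normalized-count units) added to both condition means
#: before taking the log2 ratio
LOG2FC_PSEUDOCOUNT = 0.5

LAYERS = ("mRNA", "lncRNA", "miRNA")
DIRECTIONS = ("up", "down", "none")


@dataclass(frozen=True)
class ThresholdConfig:
    """Every numeric threshold used by the downstream screens.

    Attributes
    ----------
    de_p, de_lfc:
        Differential-expression call: p < de_p and |log2FC| > de_lfc.
    dt_specific_lfc:
        Minimum |log2FC in DT| for the DT-specific drought classes (A/B).
    lfc_ratio:
        Minimum log2FC(DT)/log2FC(DS) for the shared-response classes (C/D).
    trans_r, trans_p:
        lncRNA trans-target rule: |Pearson r| > trans_r and p < trans_p.
    cis_window:
        lncRNA cis-target window in bp (boundary gap, inclusive).
    min_lnc_length, min_lnc_exons:
        lncRNA candidate filter: length > min_lnc_length nt and
        exon count >= min_lnc_exons.
    mirna_len_min, mirna_len_max:
        Acceptable mature miRNA length range in nt (inclusive).
    use_adjusted_p:
        When set, DE calls use Benjamini-Hochberg adjusted p-values.
    """

    de_p: float = 0.05
    de_lfc: float = 1.0
    dt_specific_lfc: float = 2.0
    lfc_ratio: float = 3.0
    trans_r: float = 0.9
    trans_p: float = 0.01
    cis_window: int = 100_000
    min_lnc_length: int = 200
    min_lnc_exons: int = 2
    mirna_len_min: int = 18
    mirna_len_max: int = 30
    use_adjusted_p: bool = False

    def __post_init__(self) -> None:
        for name in (
            "de_p",
            "de_lfc",
            "dt_specific_lfc",
            "lfc_ratio",
            "trans_r",
            "trans_p",
            "cis_window",
            "min_lnc_length",
            "min_lnc_exons",
            "mirna_len_min",
            "mirna_len_max",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be strictly positive")
        for name in ("de_p", "trans_p"):
            if not 0 < getattr(self, name) < 1:
                raise ValidationError(f"threshold {name} must lie in (0, 1)")
        if self.mirna_len_min > self.mirna_len_max:
            raise ValidationError("mirna_len_min must not exceed mirna_len_max")


RESULT_COLUMNS = ["feature", "layer", "genotype", "log2fc", "p", "padj", "direction"]


def _assign_directions(df: pd.DataFrame, config: ThresholdConfig) -> pd.DataFrame:
    """Set the ``direction`` column from p/log2fc under the config thresholds."""
    p = df["padj"] if config.use_adjusted_p else df["p"]
    called = (p < config.de_p) & (df["log2fc"].abs() > config.de_lfc)
    df = df.copy()
    df["direction"] = np.where(
        called & (df["log2fc"] > 0), "up", np.where(called, "down", "none")
    )
    return df


def nb_test(
    counts: ExpressionMatrix,
    genotype: str,
    config: ThresholdConfig | None = None,
    layer: str = "mRNA",
) -> pd.DataFrame:
    """NB Wald test of drought vs control within one genotype.

    Returns a data frame with one row per feature and columns
    ``feature, layer, genotype, log2fc, p, padj, direction``.  log2fc is
    drought over control on size-factor-normalized counts with a 0.5
    pseudocount; the two-sided p-value comes from the Wald statistic on the
    log fold change referred to a t distribution with n1 + n2 - 2 df.
    """
    config = config or ThresholdConfig()
    if counts.unit != "counts":
        raise ValidationError(f"nb_test requires counts, got {counts.unit}")
    ck = counts.design.samples_for(genotype, "CK")
    tr = counts.design.samples_for(genotype, "drought")
    if len(ck) < 2 or len(tr) < 2:
        raise ValidationError(
            f"genotype {genotype!r} needs >= 2 replicates per condition "
            f"(CK: {len(ck)}, drought: {len(tr)})"
        )
    sub = counts.subset_samples(ck + tr)
    sf = size_factors(sub)
    norm = sub.values.div(sf, axis=1)
    x = norm[ck].to_numpy()  # control
    y = norm[tr].to_numpy()  # drought
    n1, n2 = x.shape[1], y.shape[1]

    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx, vy = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ax = np.where(mx > 0, (vx - mx) / np.square(np.maximum(mx, 1e-300)), 0.0)
        ay = np.where(my > 0, (vy - my) / np.square(np.maximum(my, 1e-300)), 0.0)
    alpha = np.maximum((ax + ay) / 2.0, DISPERSION_FLOOR)

    c = LOG2FC_PSEUDOCOUNT
    lfc = np.log2((my + c) / (mx + c))
    # delta-method variance of log2(mean) under var(count) = mu + alpha mu^2
    var_log = (
        (1.0 / np.maximum(mx, c) + alpha) / n1 + (1.0 / np.maximum(my, c) + alpha) / n2
    ) / _LN2**2
    with np.errstate(invalid="ignore"):
        wald = lfc / np.sqrt(var_log)
    p = 2.0 * stats.t.sf(np.abs(wald), df=n1 + n2 - 2)
    p = np.where(np.isnan(p), 1.0, p)
    padj = multipletests(p, method="fdr_bh")[1]

    df = pd.DataFrame(
        {
            "feature": sub.features,
            "layer": layer,
            "genotype": genotype,
            "log2fc": lfc,
            "p": p,
            "padj": padj,
        }
    )
    return _assign_directions(df, config)


@dataclass(frozen=True)
class CallSets:
    """Per-genotype up/down differentially expressed id sets (one layer)."""

    ds_up: frozenset[str]
    ds_down: frozenset[str]
    dt_up: frozenset[str]
    dt_down: frozenset[str]

    @property
    def ds(self) -> frozenset[str]:
        return self.ds_up | self.ds_down

    @property
    def dt(self) -> frozenset[str]:
        return self.dt_up | self.dt_down


def call_sets(
    ds_results: pd.DataFrame,
    dt_results: pd.DataFrame,
    config: ThresholdConfig | None = None,
) -> CallSets:
    """Split DE results of the two genotypes into four up/down id sets.

    Calls are re-derived from the p and log2fc columns under the config
    thresholds, so the sets are reproducible from the numbers alone.  A
    feature may legitimately appear in one DS set and one DT set at once.
    """
    config = config or ThresholdConfig()
    if len(ds_results) and len(dt_results):
        if set(ds_results["layer"].unique()) != set(dt_results["layer"].unique()):
            raise ValidationError("DS and DT results must come from the same layer")
    out: dict[str, frozenset[str]] = {}
    for name, df in (("ds", ds_results), ("dt", dt_results)):
        if df["feature"].duplicated().any():
            dup = df.loc[df["feature"].duplicated(), "feature"].tolist()
            raise ValidationError(f"duplicate features in {name} results: {dup[:5]}")
        d = _assign_directions(df, config)
        out[f"{name}_up"] = frozenset(d.loc[d["direction"] == "up", "feature"])
        out[f"{name}_down"] = frozenset(d.loc[d["direction"] == "down", "feature"])
    return CallSets(**out)


@dataclass(frozen=True)
class VennCounts:
    """Two-set overlap arithmetic: common, per-set specific, union."""

    common: int
    ds_specific: int
    dt_specific: int
    union: int


def venn(ds_set: set[str] | frozenset[str], dt_set: set[str] | frozenset[str]) -> VennCounts:
    """Overlap counts between the DS and DT id sets of one layer."""
    common = len(set(ds_set) & set(dt_set))
    return VennCounts(
        common=common,
        ds_specific=len(ds_set) - common,
        dt_specific=len(dt_set) - common,
        union=len(ds_set) + len(dt_set) - common,
    )


def venn_from_sizes(n_ds: int, n_dt: int, n_common: int) -> VennCounts:
    """Overlap arithmetic from printed set sizes (|DS|, |DT|, |DS & DT|)."""
    if n_common > min(n_ds, n_dt) or min(n_ds, n_dt, n_common) < 0:
        raise ValidationError("overlap cannot exceed either set size")
    return VennCounts(
        common=n_common,
        ds_specific=n_ds - n_common,
        dt_specific=n_dt - n_common,
        union=n_ds + n_dt - n_common,
    )
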