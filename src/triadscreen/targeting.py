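"""Target-edge construction: lncRNA cis/trans targets and miRNA targets.

Three edge layers feed the module screen:

* ``lnc_cis``   — a gene within 100 kb (boundary-to-boundary gap, inclusive,
                  either direction, strand-blind) of a lncRNA on the same
                  chromosome;
* ``lnc_trans`` — a gene whose expression correlates with the lncRNA across
                  samples at |Pearson r| > 0.9 and p < 0.01;
* ``mir2mrna`` / ``mir2lnc`` — miRNA targeting relations, either ingested
                  from a precomputed table or scored with a plant-miRNA
                  complementarity penalty rubric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import ThresholdConfig
from .exceptions import DegenerateInputError, SampleMismatchError, ValidationError
from .lncannot import TranscriptRecord
from .quantify import ExpressionMatrix

EDGE_TYPES = ("mir2mrna", "mir2lnc", "lnc_cis", "lnc_trans")


@dataclass(frozen=True)
class TargetEdge:
    """A directed targeting relation between two RNA features.

    ``r``/``p`` are set on trans edges, ``distance`` (bp gap) on cis edges,
    ``score`` on complementarity-derived miRNA edges.
    """

    source: str
    target: str
    etype: str
    r: float | None = None
    p: float | None = None
    distance: int | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.etype not in EDGE_TYPES:
            raise ValidationError(f"unknown edge type {self.etype!r}")


# ---------------------------------------------------------------------------
# cis targets


def _gap(a: TranscriptRecord, b: TranscriptRecord) -> int:
    """Bases strictly between two 1-based inclusive intervals (0 if they
    touch or overlap)."""
    if a.start <= b.end and b.start <= a.end:
        return 0
    return max(a.start, b.start) - min(a.end, b.end) - 1


def cis_targets(
    lncs: list[TranscriptRecord],
    genes: list[TranscriptRecord],
    config: ThresholdConfig | None = None,
) -> list[TargetEdge]:
    """All (lncRNA, gene) pairs within the cis window on the same chromosome.

    The distance is the boundary-to-boundary gap (0 for overlapping
    features); a gap of exactly ``cis_window`` still qualifies.  Strand is
    ignored.  The scan is swept per chromosome so runtime stays near
    O(n log n) for genome-scale inputs.
    """
    config = config or ThresholdConfig()
    by_chrom: dict[str, list[TranscriptRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for v in by_chrom.values():
        v.sort(key=lambda t: t.start)
    edges: list[TargetEdge] = []
    for lnc in lncs:
        for g in by_chrom.get(lnc.chrom, ()):  # sorted by start
            if g.start > lnc.end + config.cis_window + 1:
                break
            d = _gap(lnc, g)
            if d <= config.cis_window:
                edges.append(
                    TargetEdge(source=lnc.transcript_id, target=g.transcript_id,
                               etype="lnc_cis", distance=d)
                )
    return edges


# ---------------------------------------------------------------------------
# trans targets (expression correlation)


def pearson_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-test p-value.

    p is the two-sided tail probability of t = r * sqrt((n-2) / (1-r^2))
    on n-2 degrees of freedom.  Perfectly collinear inputs give p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson_p requires two equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise ValidationError(f"pearson_p requires n >= 3 samples, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0 or sy == 0:
        raise DegenerateInputError("constant vector: correlation undefined")
    r = float(xc @ yc) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, p


def _corr_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson r between two feature x sample arrays.

    Rows with zero variance yield NaN (callers skip them)."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt((ac * ac).sum(axis=1))
    nb = np.sqrt((bc * bc).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ac @ bc.T) / np.outer(na, nb)
    return np.clip(r, -1.0, 1.0, out=r)


def trans_targets(
    lnc_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    config: ThresholdConfig | None = None,
) -> list[TargetEdge]:
    """All (lncRNA, gene) pairs with |r| > ``trans_r`` and p < ``trans_p``.

    Correlation is computed across the shared sample columns of the two
    matrices (all samples by default — per-genotype subsetting is done by
    the caller via ``subset_samples``).  Constant features are skipped.
    """
    config = config or ThresholdConfig()
    if lnc_expr.samples != gene_expr.samples:
        only_l = set(lnc_expr.samples) - set(gene_expr.samples)
        only_g = set(gene_expr.samples) - set(lnc_expr.samples)
        raise SampleMismatchError(
            "lncRNA and gene matrices must share sample columns in order; "
            f"lnc-only: {sorted(only_l)}, gene-only: {sorted(only_g)}"
        )
    n = len(lnc_expr.samples)
    if n < 3:
        raise ValidationError(f"trans correlation requires >= 3 samples, got {n}")
    a = lnc_expr.values.to_numpy(dtype=float)
    b = gene_expr.values.to_numpy(dtype=float)
    r = _corr_matrix(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) == 1.0, 0.0, p)
    hit = (np.abs(r) > config.trans_r) & (p < config.trans_p) & np.isfinite(r)
    lnc_ids = lnc_expr.features
    gene_ids = gene_expr.features
    return [
        TargetEdge(
            source=lnc_ids[i], target=gene_ids[j], etype="lnc_trans",
            r=float(r[i, j]), p=float(p[i, j]),
        )
        for i, j in zip(*np.nonzero(hit))
    ]


# ---------------------------------------------------------------------------
# miRNA target complementarity scoring

_RNA_ALPHABET = frozenset("ACGU")
_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

#: inclusive 1-based core region of the miRNA where penalties double
CORE_REGION = (2, 13)
#: default acceptance threshold on the penalty score
DEFAULT_MAX_SCORE = 4.0


def mir_target_score(mirna: str, site: str) -> float:
    """Plant-miRNA complementarity penalty between a miRNA and a site.

    The miRNA (5'->3') is aligned antiparallel to the candidate site
    (5'->3', same length): miRNA position i pairs with site position
    L - i + 1.  Watson-Crick pairs score 0, G:U wobbles 0.5, mismatches 1;
    penalties double inside the core (miRNA positions 2-13 from the 5'
    end).  Lower is better; a perfect reverse complement scores 0.
    """
    mirna = mirna.upper().replace("T", "U")
    site = site.upper().replace("T", "U")
    for name, seq in (("mirna", mirna), ("site", site)):
        bad = set(seq) - _RNA_ALPHABET
        if bad:
            raise ValidationError(f"{name} contains non-RNA symbols: {sorted(bad)}")
    if len(site) != len(mirna):
        raise ValidationError(
            f"site length {len(site)} must equal miRNA length {len(mirna)}"
        )
    score = 0.0
    L = len(mirna)
    for i, m_base in enumerate(mirna, start=1):
        s_base = site[L - i]  # antiparallel partner
        pair = (m_base, s_base)
        if pair in _PAIRS:
            penalty = 0.0
        elif pair in _WOBBLE:
            penalty = 0.5
        else:
            penalty = 1.0
        if CORE_REGION[0] <= i <= CORE_REGION[1]:
            penalty *= 2.0
        score += penalty
    return score


def scan_best_site(mirna: str, transcript: str) -> tuple[float, int]:
    """Slide the scorer along a transcript; return (best score, 0-based
    offset of the best window).  Ties break toward the 5'-most window."""
    mirna = mirna.upper().replace("T", "U")
    transcript = transcript.upper().replace("T", "U")
    L = len(mirna)
    if len(transcript) < L:
        raise ValidationError("transcript shorter than the miRNA")
    best, best_at = math.inf, 0
    for off in range(len(transcript) - L + 1):
        s = mir_target_score(mirna, transcript[off : off + L])
        if s < best:
            best, best_at = s, off
    return best, best_at


def mir_targets_from_sequences(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    etype: str,
    max_score: float = DEFAULT_MAX_SCORE,
) -> list[TargetEdge]:
    """Score every miRNA against every transcript; emit edges whose best
    site scores <= ``max_score``."""
    if etype not in ("mir2mrna", "mir2lnc"):
        raise ValidationError(f"etype must be a miRNA edge type, got {etype!r}")
    edges = []
    for mid, mseq in mirnas.items():
        for tid, tseq in transcripts.items():
            score, _ = scan_best_site(mseq, tseq)
            if score <= max_score:
                edges.append(TargetEdge(source=mid, target=tid, etype=etype,
                                        score=score))
    return edges


# ---------------------------------------------------------------------------
# edge table I/O

_EDGE_COLUMNS = ["source", "target", "type", "r", "p", "distance", "score"]


def edges_to_frame(edges: list[TargetEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "source": e.source,
                "target": e.target,
                "type": e.etype,
                "r": e.r,
                "p": e.p,
                "distance": e.distance,
                "score": e.score,
            }
            for e in edges
        ],
        columns=_EDGE_COLUMNS,
    )


def write_edges_tsv(edges: list[TargetEdge], path: str | Path) -> None:
    edges_to_frame(edges).to_csv(path, sep="\t", index=False)


def read_edges_tsv(path: str | Path) -> list[TargetEdge]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("source", "target", "type") if c not in df.columns]
    if missing:
        raise ValidationError(f"edge table missing columns: {missing}")
    def _opt(row, col, cast):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return cast(row[col])
    return [
        TargetEdge(
            source=row["source"],
            target=row["target"],
            etype=row["type"],
            r=_opt(row, "r", float),
            p=_opt(row, "p", float),
            distance=_opt(row, "distance", int),
            score=_opt(row, "score", float),
        )
        for _, row in df.iterrows()
    ]
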