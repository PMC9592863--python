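"""lncRNA candidate filtering and positional classification.

Candidate long noncoding RNAs are screened from assembled transcripts by a
consensus rule: the transcript must be of unknown/novel biotype, longer than
200 nt, multi-exonic, and voted noncoding by all four coding-potential tools
(CPC, CNCI, CPAT, Pfam — consumed here as a precomputed verdict table).

Accepted lncRNAs are then classified against the protein-coding gene models
by position and strand:

1. no overlap with any gene body          -> lincRNA (intergenic)
2. overlap with an opposite-strand gene   -> antisense
3. contained in an intron, same strand    -> intronic
4. any other same-strand exonic overlap   -> sense

Antisense is checked before intronic: strand disagreement is the stronger
signal when an lncRNA sits inside an intron of an opposite-strand gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd

from .diffexpr import ThresholdConfig
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

VERDICT_TOOLS = ("cpc", "cnci", "cpat", "pfam")
LNC_CLASSES = ("lincRNA", "intronic", "antisense", "sense")


@dataclass(frozen=True)
class TranscriptRecord:
    """One assembled transcript: coordinates (1-based inclusive), exon
    count, spliced length (nt) and biotype (``mRNA`` or ``unknown``)."""

    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exon_count: int
    length: int
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"{self.transcript_id}: start {self.start} > end {self.end}"
            )
        if self.exon_count < 1:
            raise ValidationError(f"{self.transcript_id}: exon count < 1")
        if self.length < self.exon_count:
            raise ValidationError(
                f"{self.transcript_id}: spliced length {self.length} shorter "
                f"than one base per exon ({self.exon_count} exons)"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class GeneModel:
    """A gene body with its exon intervals (1-based inclusive, sorted)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        ex = sorted(self.exons)
        return tuple(
            (a_end + 1, b_start - 1)
            for (_, a_end), (b_start, _) in zip(ex, ex[1:])
            if b_start > a_end + 1
        )


def consensus_filter(
    transcripts: list[TranscriptRecord],
    verdicts: pd.DataFrame,
    config: ThresholdConfig | None = None,
) -> set[str]:
    """Intersect the four noncoding verdicts with the structural rules.

    ``verdicts`` is indexed by transcript id with boolean/0-1 columns
    ``cpc, cnci, cpat, pfam`` where truthy means *noncoding*.  A transcript
    is accepted iff it has unknown biotype, length > ``min_lnc_length``,
    exon count >= ``min_lnc_exons``, and all four tools vote noncoding.
    """
    config = config or ThresholdConfig()
    missing_cols = [t for t in VERDICT_TOOLS if t not in verdicts.columns]
    if missing_cols:
        raise ValidationError(f"verdict table missing tool columns: {missing_cols}")
    accepted: set[str] = set()
    for tx in transcripts:
        if tx.transcript_id not in verdicts.index:
            raise ValidationError(
                f"transcript {tx.transcript_id} has no coding-potential verdict"
            )
        if tx.biotype != "unknown":
            continue
        if tx.length <= config.min_lnc_length:
            continue
        if tx.exon_count < config.min_lnc_exons:
            continue
        row = verdicts.loc[tx.transcript_id, list(VERDICT_TOOLS)]
        if bool(row.astype(bool).all()):
            accepted.add(tx.transcript_id)
    return accepted


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def classify_lnc(lnc: TranscriptRecord, genes: list[GeneModel]) -> str:
    """Assign exactly one positional class to an accepted lncRNA.

    Overlap means >= 1 bp intersection of gene-body intervals.  An lncRNA on
    a chromosome absent from the gene models is intergenic by definition
    (logged as a warning).
    """
    same_chrom = [g for g in genes if g.chrom == lnc.chrom]
    if not same_chrom and genes:
        logger.warning(
            "lncRNA %s on chromosome %s absent from gene models; "
            "classified as lincRNA",
            lnc.transcript_id,
            lnc.chrom,
        )
        return "lincRNA"
    hits = [g for g in same_chrom if _overlaps(lnc.start, lnc.end, g.start, g.end)]
    if not hits:
        return "lincRNA"
    if any(g.strand != lnc.strand for g in hits):
        return "antisense"
    for g in hits:
        for i_start, i_end in g.introns:
            if i_start <= lnc.start and lnc.end <= i_end:
                return "intronic"
    return "sense"


def classify_all(
    lncs: list[TranscriptRecord], genes: list[GeneModel]
) -> pd.DataFrame:
    """Classify every lncRNA; returns columns ``transcript, lnc_class``."""
    return pd.DataFrame(
        {
            "transcript": [t.transcript_id for t in lncs],
            "lnc_class": [classify_lnc(t, genes) for t in lncs],
        }
    )


# ---------------------------------------------------------------------------
# GTF ingestion


def read_gtf(path: str | Path) -> tuple[list[TranscriptRecord], list[GeneModel]]:
    """Read transcripts and gene models from a GTF file.

    Transcripts with ``transcript_biotype`` other than ``mRNA`` (or with the
    attribute absent) are treated as unknown/novel.  Gene models are built
    from the exon rows of transcripts whose biotype is ``mRNA``.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    transcripts: list[TranscriptRecord] = []
    genes: list[GeneModel] = []
    for tx in db.features_of_type("transcript"):
        exons = sorted(
            (e.start, e.end) for e in db.children(tx, featuretype="exon")
        )
        if not exons:
            exons = [(tx.start, tx.end)]
        biotype = tx.attributes.get("transcript_biotype", ["unknown"])[0]
        rec = TranscriptRecord(
            transcript_id=tx.id,
            chrom=tx.seqid,
            start=tx.start,
            end=tx.end,
            strand=tx.strand,
            exon_count=len(exons),
            length=sum(e - s + 1 for s, e in exons),
            biotype="mRNA" if biotype == "mRNA" else "unknown",
        )
        transcripts.append(rec)
        if rec.biotype == "mRNA":
            genes.append(
                GeneModel(
                    gene_id=tx.id,
                    chrom=tx.seqid,
                    start=tx.start,
                    end=tx.end,
                    strand=tx.strand,
                    exons=tuple(exons),
                )
            )
    return transcripts, genes


def read_verdicts(path: str | Path) -> pd.DataFrame:
    """Read a coding-potential verdict TSV (transcript + four 0/1 columns)."""
    df = pd.read_csv(path, sep="\t")
    if "transcript" not in df.columns:
        raise ValidationError("verdict table needs a 'transcript' column")
    return df.set_index("transcript")
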