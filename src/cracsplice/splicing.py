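"""Junction-spanning read classification and co-transcriptional splicing statistics.

Reads are classified against each gene's pre-mRNA and mature mRNA geometry:

* EE  — contiguous in mature-mRNA space across an exon-exon junction,
* EI / IE — contiguous in pre-mRNA space across the 5' / 3' intron boundary
  (transcript orientation), each with a minimum overhang on both sides,
* exonic / intronic otherwise, by majority base overlap.

From the per-gene EE/EI/IE tallies and the intron/exon read counts come the
splicing-efficiency statistics: the spliced ratio 2EE/(EI+IE) (>1 means
preferential recovery after splicing), its reciprocal, the pseudocounted
intron/exon ratio (I+1)/(E+1), and per-gene log2 mutant/wild-type
comparisons with coverage filtering.
"""

from __future__ import annotations

import logging
import math
import warnings
from bisect import bisect_right
from collections import defaultdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, TranscriptModel
from .preprocess import AlignedRead

log = logging.getLogger(__name__)

JUNCTION_COLUMNS = ["sample", "gene", "EE", "EI", "IE", "I", "E"]


# ---------------------------------------------------------------------------
# Read classification
# ---------------------------------------------------------------------------

def _intron_bases(blocks, introns) -> int:
    n = 0
    for bs, be in blocks:
        for is_, ie in introns:
            n += max(0, min(be, ie) - max(bs, is_))
    return n


def classify_junction_read(
    read: AlignedRead, model: TranscriptModel, min_overhang: int = 5
) -> str:
    """Label a read as EE / EI / IE / exonic / intronic / none for one gene."""
    o = min_overhang
    blocks = sorted(read.blocks)
    introns_g = sorted(
        (min(a, b), max(a, b)) for a, b in
        ((iv[0], iv[1]) for iv in model.introns)
    )
    span_s, span_e = model.span
    if blocks[-1][1] <= span_s or blocks[0][0] >= span_e:
        return "none"

    # EE: two adjacent blocks whose gap is exactly an intron, with enough
    # aligned sequence on each side of the junction
    for i in range(len(blocks) - 1):
        gap = (blocks[i][1], blocks[i + 1][0])
        if gap in introns_g:
            left = sum(e - s for s, e in blocks[: i + 1])
            right = sum(e - s for s, e in blocks[i + 1 :])
            if left >= o and right >= o:
                return "EE"

    # EI / IE: a contiguous block straddling the intron boundary.  In
    # transcript orientation the 5' boundary (exon1|intron) is the genomic
    # intron start for + genes and the intron end for - genes.
    def _covers(boundary: int) -> bool:
        return any(s <= boundary - o and e >= boundary + o for s, e in blocks)

    for is_, ie in introns_g:
        b5 = is_ if model.strand == "+" else ie
        if _covers(b5):
            return "EI"
    for is_, ie in introns_g:
        b3 = ie if model.strand == "+" else is_
        if _covers(b3):
            return "IE"

    ibases = _intron_bases(blocks, introns_g)
    ebases = sum(e - s for s, e in blocks) - ibases
    return "intronic" if ibases > ebases else "exonic"


def count_junctions(
    reads: Sequence[AlignedRead],
    ann: GenomeAnnotation,
    min_overhang: int = 5,
    sample: str = "sample",
) -> pd.DataFrame:
    """Per-gene EE/EI/IE junction tallies plus intron/exon read counts.

    A read increments I if at least one aligned base is intronic, else E
    (any intron overlap evidences an unspliced molecule).  Reads overlapping
    two genes go to the larger overlap; exact ties are dropped with a
    warning.  All genes appear in the table, so intronless genes carry
    all-zero junction counts.
    """
    by_chrom: dict[str, list[tuple[int, int, TranscriptModel]]] = defaultdict(list)
    for g in ann.genes:
        s, e = g.span
        by_chrom[g.chrom].append((s, e, g))
    for c in by_chrom:
        by_chrom[c].sort(key=lambda t: t[0])
    starts = {c: [s for s, _, _ in ivs] for c, ivs in by_chrom.items()}

    counts = {
        g.gene_id: {"EE": 0, "EI": 0, "IE": 0, "I": 0, "E": 0} for g in ann.genes
    }
    n_tied = 0
    for r in reads:
        ivs = by_chrom.get(r.chrom, [])
        if not ivs:
            continue
        lo = bisect_right(starts[r.chrom], r.start) - 1
        best, best_ov = None, 0
        tie = False
        for s, e, g in ivs[max(0, lo - 1) : lo + 3]:
            ov = sum(max(0, min(be, e) - max(bs, s)) for bs, be in r.blocks)
            if ov > best_ov:
                best, best_ov, tie = g, ov, False
            elif ov == best_ov and ov > 0 and g is not best:
                tie = True
        if best is None:
            continue
        if tie:
            n_tied += 1
            continue
        label = classify_junction_read(r, best, min_overhang)
        if label == "none":
            continue
        c = counts[best.gene_id]
        if label in ("EE", "EI", "IE"):
            c[label] += 1
        ib = _intron_bases(sorted(r.blocks), best.introns and [
            (min(a, b), max(a, b)) for a, b in best.introns
        ] or [])
        c["I" if ib > 0 else "E"] += 1
    if n_tied:
        warnings.warn(f"{n_tied} reads dropped: tied overlap between two genes")

    rows = [
        {"sample": sample, "gene": gid, **vals} for gid, vals in counts.items()
    ]
    return pd.DataFrame(rows, columns=JUNCTION_COLUMNS)


# ---------------------------------------------------------------------------
# Transcript-space alignment for RNA-seq reads
# ---------------------------------------------------------------------------

class TranscriptIndex:
    """Exact-match aligner against pre-mRNA and mature mRNA sequences.

    Spliced (exon-exon) reads are contiguous only in mature-mRNA space, so
    genomic alignment with a deletion budget cannot place them; indexing
    every read-length window of both molecule forms can.  Pre-mRNA matches
    are preferred when a read is consistent with both (purely exonic reads),
    where the two placements are genomically identical anyway.
    """

    _AMBIG = ("__ambiguous__", "", -1)

    def __init__(self, ann: GenomeAnnotation, read_length: int):
        self.ann = ann
        self.read_length = read_length
        self.lookup: dict[str, tuple[str, str, int]] = {}
        R = read_length
        for g in ann.genes:
            chrom = ann.chromosomes[g.chrom]
            pre = _oriented(chrom, *g.span, g.strand)
            mat = "".join(
                _oriented(chrom, s, e, g.strand) for s, e in g.exons
            )
            for kind, seq in (("pre", pre), ("mature", mat)):
                for t in range(len(seq) - R + 1):
                    key = seq[t : t + R]
                    cur = self.lookup.get(key)
                    if cur is None:
                        self.lookup[key] = (g.gene_id, kind, t)
                    elif cur[0] != g.gene_id:
                        self.lookup[key] = self._AMBIG
                    elif kind == "pre" and cur[1] == "mature":
                        self.lookup[key] = (g.gene_id, kind, t)

    def align(
        self, reads: Sequence[tuple[str, str]]
    ) -> tuple[list[AlignedRead], dict[str, int]]:
        out = []
        stats = {"n_unmapped": 0, "n_ambiguous": 0}
        models = {g.gene_id: g for g in self.ann.genes}
        for rid, seq in reads:
            hit = self.lookup.get(seq)
            if hit is None:
                stats["n_unmapped"] += 1
                continue
            if hit is self._AMBIG:
                stats["n_ambiguous"] += 1
                continue
            gene_id, kind, t = hit
            g = models[gene_id]
            blocks = transcript_to_genomic_blocks(
                g, t, len(seq), spliced=(kind == "mature")
            )
            out.append(
                AlignedRead(
                    read_id=rid, chrom=g.chrom, strand=g.strand,
                    blocks=blocks,
                )
            )
        return out, stats


def _oriented(chrom: str, s: int, e: int, strand: str) -> str:
    from .annotation import revcomp

    piece = chrom[s:e]
    return piece if strand == "+" else revcomp(piece)


def transcript_to_genomic_blocks(
    model: TranscriptModel, t0: int, length: int, spliced: bool
) -> tuple[tuple[int, int], ...]:
    """Genomic [start, end) blocks of molecule window [t0, t0+length)."""
    if not spliced:
        if model.strand == "+":
            return ((model.tss + t0, model.tss + t0 + length),)
        hi = model.tss - t0 + 1
        return ((hi - length, hi),)
    blocks = []
    c = 0
    for (es, ee) in model.exons:
        elen = ee - es
        lo, hi = max(t0, c), min(t0 + length, c + elen)
        if lo < hi:
            if model.strand == "+":
                blocks.append((es + (lo - c), es + (hi - c)))
            else:
                blocks.append((ee - (hi - c), ee - (lo - c)))
        c += elen
    return tuple(sorted(blocks))


# ---------------------------------------------------------------------------
# Ratio statistics
# ---------------------------------------------------------------------------

def spliced_ratio(EE: int, EI: int, IE: int) -> float:
    """2EE/(EI+IE); NA when no unspliced-junction reads exist.

    A value > 1 indicates preferential recovery after splicing.
    """
    if EI + IE == 0:
        return math.nan
    return 2.0 * EE / (EI + IE)


def unspliced_ratio(EE: int, EI: int, IE: int) -> float:
    """(EI+IE)/(2EE); NA when no spliced-junction reads exist."""
    if EE == 0:
        return math.nan
    return (EI + IE) / (2.0 * EE)


def ie_ratio(I: int, E: int) -> float:
    """(I+1)/(E+1); the pseudocount keeps the ratio finite and positive."""
    return (I + 1.0) / (E + 1.0)


_STATISTICS = {
    "ie_ratio": lambda df: (df["I"] + 1.0) / (df["E"] + 1.0),
    "unspliced_ratio": lambda df: (df["EI"] + df["IE"])
    / (2.0 * df["EE"]).replace(0.0, np.nan),
    "spliced_ratio": lambda df: 2.0 * df["EE"]
    / (df["EI"] + df["IE"]).replace(0.0, np.nan),
}


def summarize_genes(table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene summary: spliced/unspliced ratios, (I+1)/(E+1), coverage."""
    df = table.set_index("gene")
    out = pd.DataFrame(index=df.index)
    out["spliced_ratio"] = _STATISTICS["spliced_ratio"](df)
    out["unspliced_ratio"] = _STATISTICS["unspliced_ratio"](df)
    out["ie_ratio"] = _STATISTICS["ie_ratio"](df)
    out["coverage"] = df["I"] + df["E"]
    return out.reset_index()


def compare_genotypes(
    tables: Mapping[str, Sequence[pd.DataFrame]],
    statistic: str = "ie_ratio",
    numerator: str = "mut",
    denominator: str = "wt",
) -> pd.DataFrame:
    """Per-gene log2(numerator/denominator) of a splicing statistic.

    The statistic is computed per replicate per gene, averaged across
    replicates within a genotype, and the genotype averages are compared.
    Genes where any required term is NA are flagged (``defined`` False)
    rather than dropped.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    for geno in (numerator, denominator):
        if geno not in tables or not len(tables[geno]):
            raise ValueError(f"genotype {geno!r} missing from tables")
    fn = _STATISTICS[statistic]

    def _genotype_mean(dfs: Sequence[pd.DataFrame]) -> pd.Series:
        per_rep = [fn(df.set_index("gene")) for df in dfs]
        return pd.concat(per_rep, axis=1).mean(axis=1, skipna=False)

    num = _genotype_mean(tables[numerator])
    den = _genotype_mean(tables[denominator])
    genes = num.index.union(den.index)
    num, den = num.reindex(genes), den.reindex(genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2 = np.log2(num / den)
    out = pd.DataFrame(
        {
            "gene": genes,
            f"{statistic}_{numerator}": num.values,
            f"{statistic}_{denominator}": den.values,
            "log2_ratio": log2.values,
        }
    )
    out["defined"] = np.isfinite(out["log2_ratio"])
    return out


def coverage_filter(
    coverage: pd.DataFrame, mode: str = "above_mean_both", n: int | None = None
) -> list[str]:
    """Select well-covered genes from a genes x genotypes I+E table.

    ``above_mean_both`` keeps genes strictly above the mean coverage in every
    genotype; ``top_n`` keeps the n highest by mean coverage across
    genotypes, ties broken by gene id.
    """
    if coverage.empty:
        raise ValueError("empty coverage table")
    if mode == "above_mean_both":
        mask = pd.Series(True, index=coverage.index)
        for col in coverage.columns:
            mask &= coverage[col] > coverage[col].mean()
        return sorted(coverage.index[mask])
    if mode == "top_n":
        if n is None:
            raise ValueError("top_n mode requires n")
        if n > len(coverage):
            warnings.warn(f"top_n: n={n} > {len(coverage)} genes; returning all")
            n = len(coverage)
        ranking = coverage.mean(axis=1).to_frame("cov")
        ranking["gene"] = ranking.index
        ranking = ranking.sort_values(["cov", "gene"], ascending=[False, True])
        return list(ranking.index[:n])
    raise ValueError(f"unknown mode {mode!r}")


def genotype_coverage(tables: Mapping[str, Sequence[pd.DataFrame]]) -> pd.DataFrame:
    """Replicate-averaged per-gene I+E coverage, one column per genotype."""
    cols = {}
    for geno, dfs in tables.items():
        per_rep = [
            (df.set_index("gene")["I"] + df.set_index("gene")["E"]) for df in dfs
        ]
        cols[geno] = pd.concat(per_rep, axis=1).mean(axis=1)
    return pd.DataFrame(cols)


def aggregate_spliced_ratio(
    table: pd.DataFrame, weighting: str = "mean_of_ratios"
) -> float:
    """Transcriptome-level 2EE/(EI+IE).

    ``mean_of_ratios`` averages per-gene ratios over genes where the ratio is
    defined; ``pooled_counts`` computes 2*sum(EE)/sum(EI+IE).  The two can
    diverge when junction coverage is very uneven across genes.
    """
    df = table[(table["EE"] + table["EI"] + table["IE"]) > 0]
    if weighting == "mean_of_ratios":
        ratios = _STATISTICS["spliced_ratio"](df.set_index("gene")).dropna()
        return float(ratios.mean()) if len(ratios) else math.nan
    if weighting == "pooled_counts":
        denom = (df["EI"] + df["IE"]).sum()
        if denom == 0:
            return math.nan
        return float(2.0 * df["EE"].sum() / denom)
    raise ValueError(f"unknown weighting {weighting!r}")


def junction_table_to_tsv(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)
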