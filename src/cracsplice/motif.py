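"""Exact k-mer motif enrichment in crosslink-cluster sequences.

PWM/EM motif discovery is deliberately replaced by exhaustive k-mer
enumeration: the binding motif this analysis targets is a plain tetramer
(UUUG), and exact counting against a dinucleotide-preserving shuffle (or a
uniform analytic expectation) is fully reproducible.  Sequences are handled
in the DNA alphabet internally (U == T); reports render RNA.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ClusterSet
from .simulate import substream

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01  # Bonferroni-corrected over the 4^k k-mers


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass
class MotifResult:
    """Ranked k-mers with enrichment scores and the top-motif prevalence."""

    k: int
    table: pd.DataFrame  # kmer (RNA), observed, expected, score, pvalue, significant
    top_motif: str       # RNA alphabet
    fraction_containing: float
    n_sequences: int
    n_skipped: int
    background: str
    alpha: float = DEFAULT_ALPHA

    def significant_motifs(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "kmer"])


def sample_motif_sets(
    clusters: ClusterSet | Sequence[str],
    set_size: int = 500,
    n_sets: int = 2,
    seed: int = 0,
    by: str = "random",
) -> list[list[str]]:
    """Disjoint sequence sets for motif analysis (default: 2 x 500, random).

    With fewer than ``set_size`` sequences a single set holding everything is
    returned with a warning.  ``by="top_support"`` takes clusters ranked by
    supporting read count instead of sampling.
    """
    if isinstance(clusters, ClusterSet):
        if by == "top_support":
            ranked = sorted(
                clusters.clusters, key=lambda c: (-c.n_reads, c.chrom, c.start)
            )
            seqs = [c.seq for c in ranked]
        else:
            seqs = clusters.sequences()
    else:
        seqs = list(clusters)
    if len(seqs) < set_size:
        warnings.warn(
            f"only {len(seqs)} sequences available (< set_size={set_size}); "
            "returning a single set"
        )
        return [seqs]
    if by == "random":
        rng = substream(seed, "motif_sets")
        order = rng.permutation(len(seqs))
        seqs = [seqs[i] for i in order]
    n_fit = max(1, min(n_sets, len(seqs) // set_size))
    return [seqs[i * set_size : (i + 1) * set_size] for i in range(n_fit)]


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Random shuffle preserving the exact dinucleotide composition.

    Altschul-Erickson construction: pick a random terminal edge per vertex
    forming a tree into the last character, randomise the remaining edge
    orders, and walk the Euler path.
    """
    if len(seq) < 4:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    s_first, s_last = seq[0], seq[-1]
    vertices = sorted(edges)
    for _ in range(100):
        last_edge = {}
        for v in vertices:
            if v == s_last:
                continue
            last_edge[v] = edges[v][rng.integers(0, len(edges[v]))]
        ok = True
        for v in last_edge:
            seen, u = set(), v
            while u != s_last and u in last_edge and u not in seen:
                seen.add(u)
                u = last_edge[u]
            if u != s_last:
                ok = False
                break
        if not ok:
            continue
        pools = {}
        for v in vertices:
            pool = list(edges[v])
            if v in last_edge:
                pool.remove(last_edge[v])
            rng.shuffle(pool)
            if v in last_edge:
                pool.append(last_edge[v])
            pools[v] = pool
        out = [s_first]
        idx = dict.fromkeys(vertices, 0)
        u = s_first
        for _ in range(len(seq) - 1):
            nxt = pools[u][idx[u]]
            idx[u] += 1
            out.append(nxt)
            u = nxt
        return "".join(out)
    return seq  # degenerate composition; identity is a valid shuffle


def _count_kmers(seqs: Sequence[str], k: int) -> tuple[Counter, int, int]:
    counts: Counter = Counter()
    windows = 0
    skipped = 0
    for s in seqs:
        if len(s) < k:
            skipped += 1
            continue
        for i in range(len(s) - k + 1):
            counts[s[i : i + k]] += 1
        windows += len(s) - k + 1
    return counts, windows, skipped


def kmer_enrichment(
    sequences: Sequence[str],
    k: int = 4,
    background: str = "shuffle_dinucleotide",
    n_shuffles: int = 10,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
) -> MotifResult:
    """Rank all k-mers by log2 observed/expected against a null background.

    Expected counts come either from the mean over dinucleotide-preserving
    shuffles of the input, or from the uniform analytic expectation
    (windows / 4^k).  The surprise value is a one-sided pooled binomial tail;
    significance uses a Bonferroni correction over the 4^k k-mers.  Ranking
    is deterministic: score descending, then lexicographic.
    """
    if not sequences:
        raise ValueError("no sequences")
    if k < 2:
        raise ValueError("k must be >= 2")
    seqs = [_dna(s) for s in sequences]
    obs, windows, skipped = _count_kmers(seqs, k)
    if skipped:
        log.warning("%d sequences shorter than k=%d skipped", skipped, k)
    if windows == 0:
        raise ValueError("all sequences shorter than k")

    all_kmers = ["".join(p) for p in product("ACGT", repeat=k)]
    if background == "uniform":
        expected = {km: windows / 4**k for km in all_kmers}
    elif background == "shuffle_dinucleotide":
        rng = substream(seed, "kmer_shuffle")
        acc: Counter = Counter()
        for _ in range(n_shuffles):
            shuffled = [dinucleotide_shuffle(s, rng) for s in seqs]
            c, _, _ = _count_kmers(shuffled, k)
            acc.update(c)
        expected = {km: acc.get(km, 0) / n_shuffles for km in all_kmers}
    else:
        raise ValueError(f"unknown background {background!r}")

    rows = []
    n_tests = 4**k
    for km in all_kmers:
        o = obs.get(km, 0)
        e = expected[km]
        score = float(np.log2((o + 0.5) / (e + 0.5)))
        p0 = min(1.0, (e + 0.5) / (windows + 0.5))
        pval = float(stats.binom.sf(o - 1, windows, p0)) if o > 0 else 1.0
        rows.append((km, o, e, score, pval))
    df = pd.DataFrame(rows, columns=["kmer", "observed", "expected", "score", "pvalue"])
    df["significant"] = df["pvalue"] < alpha / n_tests
    df = df.sort_values(["score", "kmer"], ascending=[False, True]).reset_index(drop=True)
    top = df.iloc[0]["kmer"]
    df["kmer"] = df["kmer"].map(_rna)
    return MotifResult(
        k=k,
        table=df,
        top_motif=_rna(top),
        fraction_containing=fraction_containing(seqs, top),
        n_sequences=len(seqs),
        n_skipped=skipped,
        background=background,
        alpha=alpha,
    )


def fraction_containing(sequences: Sequence[str], motif: str) -> float:
    """Share of sequences with at least one exact motif occurrence (U == T)."""
    if not motif:
        raise ValueError("motif must be non-empty")
    if not sequences:
        return float("nan")
    m = _dna(motif)
    hits = sum(1 for s in sequences if m in _dna(s))
    return hits / len(sequences)


def motif_table_to_tsv(result: MotifResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# k={result.k} background={result.background} "
            f"n_sequences={result.n_sequences} top={result.top_motif} "
            f"fraction_containing={result.fraction_containing!r} "
            f"bonferroni_alpha={result.alpha}/{4**result.k}\n"
        )
        result.table.to_csv(fh, sep="\t", index=False)
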