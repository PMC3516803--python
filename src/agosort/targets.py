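"""Target-set overlap expectations and GO-slim enrichment for AGO classes.

Target lists (from an external miRNA-target predictor) are compared between
AGO classes: the expected random overlap between two target sets drawn from
a genome of N genes is n1*n2/N, and term enrichment of one AGO's targets
against another's uses Fisher's exact test with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import fisher_exact

from .confidence import ConfidenceSet
from .stats import bh_fdr

DEFAULT_GENOME_SIZE = 30000  # approximate A. thaliana gene count


def expected_overlap(n1: int, n2: int, genome_size: int = DEFAULT_GENOME_SIZE) -> float:
    """Expected number of shared targets between two random gene sets of
    sizes n1 and n2 drawn from ``genome_size`` genes: n1*n2/N."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if n1 > genome_size or n2 > genome_size:
        raise ValueError("set size exceeds genome size")
    return n1 * n2 / genome_size


def dedup_20mers(cset: ConfidenceSet | Sequence[str]) -> list[str]:
    """Truncate 21-mers to 5'-anchored 20-mers and drop duplicates.

    Members of large miRNA families often differ only near the 3' end;
    collapsing on 20-mers before target prediction keeps family bias out of
    downstream enrichment.  First occurrence wins.
    """
    seqs = cset.aligned21()[0] if isinstance(cset, ConfidenceSet) else list(cset)
    seen: set[str] = set()
    out: list[str] = []
    for s in seqs:
        s20 = s[:20]
        if s20 not in seen:
            seen.add(s20)
            out.append(s20)
    return out


def fisher_enrichment(
    focal_targets: Iterable[str],
    background_targets: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    alternative: str = "two-sided",
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-term Fisher exact enrichment of focal vs. background targets.

    Shared targets are removed from both sets first (the comparison is
    between the disjoint target sets), and the universe is the union of
    the two disjoint sets.  For each annotated term the 2x2 table is
    (focal vs. background) x (has term vs. not); BH-FDR is applied across
    terms and rows with p_fdr below ``fdr_threshold`` flagged significant.
    """
    focal = set(focal_targets)
    background = set(background_targets)
    if not focal:
        raise ValueError("empty focal target set")
    shared = focal & background
    focal -= shared
    background -= shared
    if not focal or not background:
        raise ValueError("no disjoint targets left after shared-target removal")

    terms: set[str] = set()
    for gene in focal | background:
        terms.update(annotation.get(gene, ()))
    rows = []
    for term in sorted(terms):
        with_term = {g for g in focal | background if term in set(annotation.get(g, ()))}
        a = len(focal & with_term)
        b = len(focal - with_term)
        c = len(background & with_term)
        d = len(background - with_term)
        p = float(fisher_exact([[a, b], [c, d]], alternative=alternative).pvalue)
        rows.append({"term": term, "a": a, "b": b, "c": c, "d": d, "p": p})
    df = pd.DataFrame(rows, columns=["term", "a", "b", "c", "d", "p"])
    if len(df):
        df["p_fdr"] = bh_fdr(df["p"].to_numpy())
        df["significant"] = df["p_fdr"] < fdr_threshold
    else:
        df["p_fdr"] = []
        df["significant"] = []
    return df


def read_target_list(path: str) -> list[str]:
    """One gene id per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_annotation(path: str) -> dict[str, set[str]]:
    """Two-column TSV (gene, term) into a gene -> terms mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"])
    out: dict[str, set[str]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.gene), set()).add(str(row.term))
    return out
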