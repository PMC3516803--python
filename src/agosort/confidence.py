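"""From raw co-IP reads to the labeled confidence set of AGO-sorted miRNAs.

The confidence set is the non-redundant collection of mature miRNAs whose
sequencing reads show a clear preference (> 70% read share at >= 10 RPM
total) for a single Argonaute co-IP library.  Sequences are 5'-anchored and
trimmed to 21 nt for positional analyses, reflecting the anchoring of the
miRNA 5' terminus in the AGO MID domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountTable, MiRNARecord, RpmTable, to_rna

logger = logging.getLogger("agosort")


def trim_reads(reads: Iterable[str], adapter: str, max_len: int = 30) -> list[str]:
    """Remove a 3' adapter by exact substring search, then cap read length.

    The first occurrence of the adapter is searched in each read; everything
    from it onward is dropped.  Reads are then truncated to ``max_len``
    (reads whose adapter was only partially sequenced keep an adapter stub,
    which is harmless for substring-based counting).  Reads empty after
    trimming are dropped and their number logged.
    """
    adapter = to_rna(adapter)
    out: list[str] = []
    n_empty = 0
    for read in reads:
        read = to_rna(read)
        hit = read.find(adapter)
        if hit >= 0:
            read = read[:hit]
        read = read[:max_len]
        if read:
            out.append(read)
        else:
            n_empty += 1
    if n_empty:
        logger.info("trim_reads: dropped %d empty post-trim reads", n_empty)
    return out


def count_reads(
    reads_per_library: Mapping[str, Sequence[str]],
    mirnas: Sequence[MiRNARecord] | Mapping[str, str],
) -> CountTable:
    """Count reads containing each mature miRNA as an exact substring.

    Identical mature sequences share a single row (first id kept).  A read
    containing several distinct mature sequences increments each of them:
    miRNAs are matched against reads independently, with no unique
    per-read assignment.  Library totals are the per-library read counts.
    """
    if isinstance(mirnas, Mapping):
        id_seq = [(mid, to_rna(seq)) for mid, seq in mirnas.items()]
    else:
        id_seq = [(rec.id, rec.mature_seq) for rec in mirnas]
    if not id_seq:
        raise ValueError("empty miRNA list")

    seq_to_row: dict[str, int] = {}
    row_ids: list[str] = []
    row_seqs: list[str] = []
    for mid, seq in id_seq:
        if seq in seq_to_row:
            logger.info("count_reads: %s shares a sequence with %s, merged", mid, row_ids[seq_to_row[seq]])
            continue
        seq_to_row[seq] = len(row_ids)
        row_ids.append(mid)
        row_seqs.append(seq)

    libs = list(reads_per_library)
    counts = np.zeros((len(row_ids), len(libs)), dtype=np.int64)
    totals = np.zeros(len(libs), dtype=np.int64)
    for j, lib in enumerate(libs):
        reads = [to_rna(r) for r in reads_per_library[lib]]
        totals[j] = len(reads)
        # Group identical reads once; co-IP libraries are highly redundant.
        uniq: dict[str, int] = {}
        for r in reads:
            uniq[r] = uniq.get(r, 0) + 1
        for r, mult in uniq.items():
            for i, seq in enumerate(row_seqs):
                if seq in r:
                    counts[i, j] += mult
    return CountTable(
        mirna_ids=row_ids,
        library_ids=libs,
        counts=counts,
        library_totals=np.maximum(totals, 1),
        totals_provenance="given",
    )


def normalize_rpm(table: CountTable) -> RpmTable:
    """Reads-per-million: count / library total x 1e6."""
    if np.any(table.library_totals <= 0):
        raise ValueError("zero library total")
    rpm = table.counts / table.library_totals[None, :] * 1e6
    return RpmTable(mirna_ids=list(table.mirna_ids), library_ids=list(table.library_ids), rpm=rpm)


def assign_preference(
    rpm: RpmTable,
    min_rpm: float = 10.0,
    threshold: float = 0.70,
    shares_from: CountTable | None = None,
) -> pd.DataFrame:
    """Assign each miRNA an AGO label, or an excluded/ambiguous status.

    miRNAs whose summed RPM over all libraries is below ``min_rpm`` are
    excluded (strict: < min_rpm).  Otherwise, if one library holds strictly
    more than ``threshold`` of the miRNA's summed signal it gets that AGO
    label; otherwise the miRNA is ambiguous.  Shares are computed on the RPM
    matrix by default; pass ``shares_from`` to compute them on raw counts
    instead (the two differ when library depths differ).
    """
    share_mat = rpm.rpm if shares_from is None else shares_from.counts.astype(float)
    rpm_total = rpm.rpm.sum(axis=1)
    rows = []
    for i, mid in enumerate(rpm.mirna_ids):
        total = share_mat[i].sum()
        if rpm_total[i] < min_rpm:
            rows.append((mid, "excluded", "", 0.0, rpm_total[i]))
            continue
        shares = share_mat[i] / total if total > 0 else np.zeros_like(share_mat[i])
        best = int(np.argmax(shares))
        if shares[best] > threshold:
            rows.append((mid, "labeled", rpm.library_ids[best], float(shares[best]), rpm_total[i]))
        else:
            rows.append((mid, "ambiguous", "", float(shares[best]), rpm_total[i]))
    return pd.DataFrame(rows, columns=["mirna_id", "status", "ago_label", "preference_fraction", "rpm_total"])


@dataclass
class SortedMiRNA:
    """One confidence-set member: a mature miRNA with its AGO assignment."""

    id: str
    full_seq: str
    ago_label: str
    preference_fraction: float
    rpm_total: float
    seq21: str | None = None  # 5'-anchored 21-mer; None when the mature sequence is shorter

    def __post_init__(self) -> None:
        if len(self.full_seq) >= 21 and self.seq21 is None:
            self.seq21 = self.full_seq[:21]


@dataclass
class ConfidenceSet:
    """Non-redundant AGO-labeled miRNAs.

    ``entries`` keeps the full mature sequences (used 24-nt N-padded by the
    forest classifier); :meth:`aligned21` yields the 5'-anchored 21-mers
    used by positional statistics, excluding members shorter than 21 nt.
    """

    entries: list[SortedMiRNA] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries:
            out[e.ago_label] = out.get(e.ago_label, 0) + 1
        return out

    def subset(self, classes: Sequence[str]) -> "ConfidenceSet":
        keep = set(classes)
        return ConfidenceSet([e for e in self.entries if e.ago_label in keep])

    def aligned21(self) -> tuple[list[str], list[str]]:
        """(sequences, labels) of the 21-mer-trimmed members."""
        seqs, labels = [], []
        for e in self.entries:
            if e.seq21 is not None:
                seqs.append(e.seq21)
                labels.append(e.ago_label)
        return seqs, labels

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mirna_id": [e.id for e in self.entries],
                "seq21": [e.seq21 or "" for e in self.entries],
                "full_seq": [e.full_seq for e in self.entries],
                "ago_label": [e.ago_label for e in self.entries],
                "preference_fraction": [e.preference_fraction for e in self.entries],
                "rpm_total": [e.rpm_total for e in self.entries],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_confidence_tsv(path: str | Path) -> ConfidenceSet:
    """Load a confidence set written by :meth:`ConfidenceSet.write_tsv`."""
    df = pd.read_csv(path, sep="\t")
    entries = [
        SortedMiRNA(
            id=str(row.mirna_id),
            full_seq=to_rna(str(row.full_seq)),
            ago_label=str(row.ago_label),
            preference_fraction=float(row.preference_fraction),
            rpm_total=float(row.rpm_total),
        )
        for row in df.itertuples()
    ]
    return ConfidenceSet(entries)


def build_confidence_set(
    assignments: pd.DataFrame,
    mirnas: Sequence[MiRNARecord] | Mapping[str, str],
    precursor_filter: Mapping[str, tuple[bool, str | None]] | None = None,
) -> ConfidenceSet:
    """Assemble the confidence set from preference labels and filter verdicts.

    Keeps labeled miRNAs whose precursor passed the duplex quality filter,
    deduplicates identical mature sequences (first id kept, merges logged;
    identical sequences with conflicting labels are an error since read
    counting operates on the sequence), and records 5'-anchored 21-mers.
    """
    if isinstance(mirnas, Mapping):
        seq_of = {mid: to_rna(seq) for mid, seq in mirnas.items()}
    else:
        seq_of = {rec.id: rec.mature_seq for rec in mirnas}

    labeled = assignments[assignments["status"] == "labeled"]
    by_seq: dict[str, SortedMiRNA] = {}
    for row in labeled.itertuples():
        mid = row.mirna_id
        if mid not in seq_of:
            logger.warning("build_confidence_set: no sequence for %s, skipped", mid)
            continue
        if precursor_filter is not None:
            ok, reason = precursor_filter.get(mid, (True, None))
            if not ok:
                logger.info("build_confidence_set: %s failed precursor filter (%s)", mid, reason)
                continue
        seq = seq_of[mid]
        if seq in by_seq:
            prev = by_seq[seq]
            if prev.ago_label != row.ago_label:
                raise ValueError(
                    f"identical mature sequence with conflicting labels: "
                    f"{prev.id}={prev.ago_label}, {mid}={row.ago_label}"
                )
            logger.info("build_confidence_set: %s duplicates %s, merged", mid, prev.id)
            continue
        by_seq[seq] = SortedMiRNA(
            id=str(mid),
            full_seq=seq,
            ago_label=str(row.ago_label),
            preference_fraction=float(row.preference_fraction),
            rpm_total=float(row.rpm_total),
        )

    entries = list(by_seq.values())
    # Distinct full sequences can still share a 21-mer prefix; the 21-mer
    # view must be non-redundant, so later duplicates are dropped entirely.
    seen21: dict[str, str] = {}
    kept: list[SortedMiRNA] = []
    for e in entries:
        if e.seq21 is not None and e.seq21 in seen21:
            logger.info("build_confidence_set: %s shares a 21-mer with %s, dropped", e.id, seen21[e.seq21])
            continue
        if e.seq21 is not None:
            seen21[e.seq21] = e.id
        else:
            logger.info("build_confidence_set: %s shorter than 21 nt, kept for padded analyses only", e.id)
        kept.append(e)
    return ConfidenceSet(kept)
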