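"""Input/output for miRNA sequence sets, co-IP count tables, and run reports.

All sequences are held internally in the RNA alphabet (A/C/G/U, uppercase);
DNA input is transliterated on load.  Coordinates are 1-based inclusive,
counting from the 5' end, which is the convention used throughout the
package (position 1 is the 5'-terminal nucleotide recognised by the AGO
MID domain).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("agosort")

RNA_BASES = "ACGU"
_TO_RNA = str.maketrans("acgutTnN", "ACGUUUNN")

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def to_rna(seq: str) -> str:
    """Uppercase a sequence and transliterate T to U."""
    return seq.translate(_TO_RNA)


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MiRNARecord:
    """One miRNA locus: mature/star sequences and their precursor coordinates.

    ``mature_start``/``mature_end`` (and the star equivalents) are 1-based
    inclusive positions on the precursor.
    """

    id: str
    mature_seq: str
    precursor_seq: str
    mature_start: int
    mature_end: int
    star_seq: str | None = None
    star_start: int | None = None
    star_end: int | None = None

    def validate(self) -> None:
        if not (1 <= self.mature_start <= self.mature_end <= len(self.precursor_seq)):
            raise ValueError(
                f"{self.id}: mature span {self.mature_start}..{self.mature_end} "
                f"outside precursor of length {len(self.precursor_seq)}"
            )
        sub = self.precursor_seq[self.mature_start - 1 : self.mature_end]
        if sub != self.mature_seq:
            raise ValueError(f"{self.id}: mature sequence does not match precursor span")
        if self.star_start is not None:
            if self.star_end is None or not (
                1 <= self.star_start <= self.star_end <= len(self.precursor_seq)
            ):
                raise ValueError(f"{self.id}: invalid star span")
            star_sub = self.precursor_seq[self.star_start - 1 : self.star_end]
            if self.star_seq is not None and star_sub != self.star_seq:
                raise ValueError(f"{self.id}: star sequence does not match precursor span")
        for seq in (self.mature_seq, self.precursor_seq, self.star_seq or ""):
            bad = set(seq) - set("ACGUN")
            if bad:
                raise ValueError(f"{self.id}: non-RNA characters {sorted(bad)}")


@dataclass
class CountTable:
    """miRNA x library matrix of raw read counts.

    ``library_totals`` are the per-library denominators used for RPM
    normalization.  ``totals_provenance`` records whether they were supplied
    explicitly ("given") or derived as column sums ("derived") — the two
    differ whenever libraries contain reads not assigned to any miRNA.
    """

    mirna_ids: list[str]
    library_ids: list[str]
    counts: np.ndarray
    library_totals: np.ndarray
    totals_provenance: str = "given"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.library_totals = np.asarray(self.library_totals)
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA ids in count table")
        if len(set(self.library_ids)) != len(self.library_ids):
            raise ValueError("duplicate library ids in count table")
        if self.counts.shape != (len(self.mirna_ids), len(self.library_ids)):
            raise ValueError("count matrix shape does not match id lists")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if np.any(self.library_totals <= 0):
            raise ValueError("library totals must be positive")
        if np.any(self.counts > self.library_totals[None, :]):
            raise ValueError("count exceeds its library total")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.mirna_ids, columns=self.library_ids)


@dataclass
class RpmTable:
    """miRNA x library matrix in reads-per-million."""

    mirna_ids: list[str]
    library_ids: list[str]
    rpm: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rpm, index=self.mirna_ids, columns=self.library_ids)


@dataclass
class RunConfig:
    """Thresholds and algorithm parameters for a pipeline run.

    Defaults follow the analysis protocol this package implements: miRNAs
    with < 10 RPM are excluded, a > 70% read share defines an AGO
    preference, precursors with > 6 mismatches or a bulge > 3 nt are
    discarded, forests use 500 trees with a balanced per-class bootstrap of
    20, and positional mutual information is tested against 10,000 label
    shuffles.
    """

    min_rpm: float = 10.0
    preference_fraction: float = 0.70
    max_mismatches: int = 6
    max_bulge: int = 3
    n_trees: int = 500
    sampsize: int = 20
    n_runs: int = 1000
    n_perm: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.preference_fraction < 1:
            raise ValueError("preference_fraction must be in (0,1)")
        if self.min_rpm < 0:
            raise ValueError("min_rpm must be non-negative")
        for name in ("max_mismatches", "max_bulge", "n_trees", "sampsize", "n_runs", "n_perm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _read_fasta(paths: Iterable[str | Path]) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for path in paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
            seqs[rec.id] = to_rna(str(rec.seq))
    return seqs


def load_mirna_set(
    fasta_paths: Sequence[str | Path],
    coordinate_table: str | Path | pd.DataFrame,
) -> list[MiRNARecord]:
    """Load miRNA records from FASTA files plus a coordinate table.

    The coordinate table (TSV with columns mirna_id, precursor_id, start,
    end, arm) maps mature and star sequences onto their precursors.  Records
    whose coordinates fall outside the precursor, or whose FASTA sequence
    disagrees with the precursor span, are rejected with a logged reason
    rather than raising.  Duplicate mature ids are an error.
    """
    seqs = _read_fasta(fasta_paths)
    if isinstance(coordinate_table, pd.DataFrame):
        coords = coordinate_table
    else:
        coords = pd.read_csv(coordinate_table, sep="\t")
    required = {"mirna_id", "precursor_id", "start", "end", "arm"}
    missing = required - set(coords.columns)
    if missing:
        raise ValueError(f"coordinate table missing columns {sorted(missing)}")

    mature_rows = coords[coords["arm"] == "mature"]
    star_rows = coords[coords["arm"] == "star"].set_index("precursor_id")
    if mature_rows["mirna_id"].duplicated().any():
        dups = mature_rows.loc[mature_rows["mirna_id"].duplicated(), "mirna_id"].tolist()
        raise ValueError(f"duplicate mature mirna_id entries: {dups}")

    records: list[MiRNARecord] = []
    for row in mature_rows.itertuples():
        prec_id = row.precursor_id
        if prec_id not in seqs:
            logger.warning("rejecting %s: precursor %s not in FASTA", row.mirna_id, prec_id)
            continue
        prec = seqs[prec_id]
        start, end = int(row.start), int(row.end)
        if not (1 <= start <= end <= len(prec)):
            logger.warning(
                "rejecting %s: mature span %d..%d outside precursor of length %d",
                row.mirna_id, start, end, len(prec),
            )
            continue
        mature = prec[start - 1 : end]
        if row.mirna_id in seqs and seqs[row.mirna_id] != mature:
            logger.warning("rejecting %s: FASTA sequence disagrees with precursor span", row.mirna_id)
            continue
        rec = MiRNARecord(
            id=str(row.mirna_id),
            mature_seq=mature,
            precursor_seq=prec,
            mature_start=start,
            mature_end=end,
        )
        if prec_id in star_rows.index:
            srow = star_rows.loc[prec_id]
            s_start, s_end = int(srow["start"]), int(srow["end"])
            if 1 <= s_start <= s_end <= len(prec):
                rec.star_seq = prec[s_start - 1 : s_end]
                rec.star_start = s_start
                rec.star_end = s_end
            else:
                logger.warning("%s: star span %d..%d outside precursor, dropped", rec.id, s_start, s_end)
        rec.validate()
        records.append(rec)
    return records


def read_count_table(
    tsv_path: str | Path,
    totals_path: str | Path | None = None,
) -> CountTable:
    """Read a miRNA x library count table from TSV.

    First column holds miRNA ids, header row the library ids.  Per-library
    totals come from an optional two-column sidecar (library_id, total); when
    absent they are computed as column sums and flagged as "derived".
    """
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    for col in df.columns:
        for row_id, val in df[col].items():
            if isinstance(val, float) and not float(val).is_integer():
                raise ValueError(f"non-integer count at row {row_id!r}, column {col!r}")
            if int(val) < 0:
                raise ValueError(f"negative count at row {row_id!r}, column {col!r}")
    counts = df.to_numpy().astype(np.int64)
    if totals_path is not None:
        tot = pd.read_csv(totals_path, sep="\t", header=None, index_col=0)[1]
        totals = np.array([int(tot[lib]) for lib in df.columns])
        provenance = "given"
    else:
        totals = counts.sum(axis=0)
        provenance = "derived"
    return CountTable(
        mirna_ids=[str(i) for i in df.index],
        library_ids=[str(c) for c in df.columns],
        counts=counts,
        library_totals=totals,
        totals_provenance=provenance,
    )


def write_count_table(table: CountTable, tsv_path: str | Path, totals_path: str | Path | None = None) -> None:
    table.to_frame().to_csv(tsv_path, sep="\t")
    if totals_path is not None:
        with open(totals_path, "w") as fh:
            for lib, tot in zip(table.library_ids, table.library_totals):
                fh.write(f"{lib}\t{int(tot)}\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_report(
    results: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
    extra: Mapping[str, object] | None = None,
) -> dict:
    """Write result tables as TSV plus a JSON run manifest.

    Every entry in ``results`` becomes ``<name>.tsv`` with a deterministic
    column order (as given in the frame).  Empty frames still produce a
    header-only file.  Returns the manifest dictionary, which is also
    written to ``run_manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict() if config is not None else None,
        "seed": seed,
        "outputs": {},
    }
    if extra:
        manifest.update(dict(extra))
    for name in sorted(results):
        path = out / f"{name}.tsv"
        results[name].to_csv(path, sep="\t", index=False)
        manifest["outputs"][name] = {"path": str(path), "sha256": file_sha256(path)}
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
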