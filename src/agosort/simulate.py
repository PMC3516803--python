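"""Synthetic co-IP data with planted Argonaute sorting signals.

This module generates everything the downstream analysis consumes — labeled
mature miRNA sequences, hairpin precursors with controlled duplex defects,
and per-AGO sequencing libraries — so that the whole pipeline can be
exercised and calibrated without external data.

The statistical structure mimics small-RNA co-immunoprecipitation
experiments: each miRNA has a latent AGO class; its reads distribute over
the AGO libraries according to a Dirichlet-multinomial whose concentration
controls how sharp the sorting preference is; class-conditional base
distributions at chosen positions plant univariate sorting signals, and
nested conditional rules plant higher-order (two-position) signals that a
univariate statistic cannot see but a decision-tree ensemble can.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import RNA_BASES, CountTable, MiRNARecord, to_rna

logger = logging.getLogger("agosort")

ALL_CLASSES = ("AGO1", "AGO2", "AGO4", "AGO5")

# Illumina small-RNA 3' adapter, in RNA alphabet.
DEFAULT_ADAPTER = "UGGAAUUCUCGGGUGCCAAGG"

_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {"G": "U", "U": "G"}

_UNIFORM = {b: 0.25 for b in RNA_BASES}


def _check_dist(dist: Mapping[str, float], where: str) -> None:
    if set(dist) - set(RNA_BASES):
        raise ValueError(f"{where}: bases outside ACGU")
    if abs(sum(dist.values()) - 1.0) > 1e-9:
        raise ValueError(f"{where}: distribution does not sum to 1")


@dataclass(frozen=True)
class NestedRule:
    """A conditional two-position sorting rule.

    Sequences of both outcome classes carry a base from ``condition_bases``
    at ``condition_pos``; the class is decided by whether the base at
    ``decision_pos`` falls in ``decision_bases``.  This encodes signals of
    the form "5'-C with G/U at position 9 goes to AGO1, otherwise to AGO5",
    which are invisible to any single-position statistic once the condition
    position is shared between the classes.
    """

    condition_pos: int
    condition_bases: frozenset
    decision_pos: int
    decision_bases: frozenset
    class_if_true: str
    class_if_false: str


@dataclass
class SignalSpec:
    """Class structure and planted positional signals for sequence generation.

    ``position_signals`` maps a 1-based position to per-class base
    distributions; classes absent from a position draw from ``background``
    there.  Positions must lie in 1..24.
    """

    class_names: list[str]
    n_per_class: dict[str, int]
    position_signals: dict[int, dict[str, dict[str, float]]] = field(default_factory=dict)
    nested_rules: list[NestedRule] = field(default_factory=list)
    background: dict[str, float] = field(default_factory=lambda: dict(_UNIFORM))

    def __post_init__(self) -> None:
        _check_dist(self.background, "background")
        for pos, per_class in self.position_signals.items():
            if not 1 <= pos <= 24:
                raise ValueError(f"signal position {pos} outside 1..24")
            for cls, dist in per_class.items():
                _check_dist(dist, f"position {pos}, class {cls}")
        for cls in self.class_names:
            if self.n_per_class.get(cls, 0) <= 0:
                raise ValueError(f"class {cls} has no sample size")
        for rule in self.nested_rules:
            for cls in (rule.class_if_true, rule.class_if_false):
                for pos in (rule.condition_pos, rule.decision_pos):
                    if cls in self.position_signals.get(pos, {}):
                        raise ValueError(
                            f"nested rule on position {pos} conflicts with a "
                            f"position signal for class {cls}"
                        )


@dataclass
class LibrarySpec:
    """Sequencing-library layout for read generation.

    ``library_sizes`` sets the approximate sequencing depth per AGO library;
    ``preference_strength`` is the Dirichlet concentration placed on a
    miRNA's own class (the remaining classes share a unit concentration
    each), so large values give near-exclusive sorting and values near 1
    give noisy, promiscuous association.  ``noise_fraction`` of each
    library's reads are random sequences matching no miRNA, emulating
    unassignable reads.
    """

    library_ids: tuple = ALL_CLASSES
    library_sizes: dict[str, int] | None = None
    preference_strength: float = 20.0
    noise_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.library_sizes is None:
            # Relative depths of the four AGO co-IP libraries, scaled to a
            # tractable total of ~70k reads.
            full = {"AGO1": 3241388, "AGO2": 771808, "AGO4": 2148570, "AGO5": 874751}
            self.library_sizes = {k: full[k] // 100 for k in self.library_ids}
        if any(v <= 0 for v in self.library_sizes.values()):
            raise ValueError("library sizes must be positive")
        if self.preference_strength <= 0:
            raise ValueError("preference_strength must be positive")
        if not 0 <= self.noise_fraction < 1:
            raise ValueError("noise_fraction must be in [0,1)")


def table1_signal_spec(three_class: bool = False) -> SignalSpec:
    """The default study conditions: a 5'-base sorting signal.

    Class sizes (70/25/9/22) and class-conditional 5'-base distributions
    reproduce the observed composition of the AGO co-IP confidence set:
    AGO1 dominated by 5'-U, AGO2 and AGO4 by 5'-A, AGO5 split between 5'-C
    and 5'-U.  All other positions draw from the background distribution.
    """
    first_base = {
        "AGO1": {"A": 0.0, "C": 6 / 70, "G": 1 / 70, "U": 63 / 70},
        "AGO2": {"A": 21 / 25, "C": 0.0, "G": 1 / 25, "U": 3 / 25},
        "AGO4": {"A": 5 / 9, "C": 0.0, "G": 0.0, "U": 4 / 9},
        "AGO5": {"A": 0.0, "C": 6 / 22, "G": 0.0, "U": 16 / 22},
    }
    sizes = {"AGO1": 70, "AGO2": 25, "AGO4": 9, "AGO5": 22}
    classes = ["AGO1", "AGO2", "AGO5"] if three_class else ["AGO1", "AGO2", "AGO4", "AGO5"]
    return SignalSpec(
        class_names=classes,
        n_per_class={c: sizes[c] for c in classes},
        position_signals={1: {c: first_base[c] for c in classes}},
    )


def generate_sequences(
    spec: SignalSpec, length: int = 21, seed: int | np.random.Generator = 0
) -> tuple[list[str], list[str]]:
    """Draw labeled mature sequences with the planted signals.

    Returns (sequences, labels) in class order.  Background positions are
    i.i.d. from ``spec.background``; signal positions follow the
    class-conditional distributions; nested rules then overwrite their
    condition and decision positions as described in :class:`NestedRule`.
    """
    max_pos = max(
        [0]
        + list(spec.position_signals)
        + [p for r in spec.nested_rules for p in (r.condition_pos, r.decision_pos)]
    )
    if length < max_pos:
        raise ValueError(f"length {length} shorter than maximum signal position {max_pos}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bases = np.array(list(RNA_BASES))
    bg_p = np.array([spec.background[b] for b in RNA_BASES])

    seqs: list[str] = []
    labels: list[str] = []
    for cls in spec.class_names:
        n = spec.n_per_class[cls]
        mat = rng.choice(4, size=(n, length), p=bg_p)
        for pos, per_class in spec.position_signals.items():
            if cls in per_class:
                p = np.array([per_class[cls][b] for b in RNA_BASES])
                mat[:, pos - 1] = rng.choice(4, size=n, p=p)
        for rule in spec.nested_rules:
            if cls not in (rule.class_if_true, rule.class_if_false):
                continue
            cond = sorted(rule.condition_bases)
            mat[:, rule.condition_pos - 1] = [
                list(RNA_BASES).index(b) for b in rng.choice(cond, size=n)
            ]
            if cls == rule.class_if_true:
                dec = sorted(rule.decision_bases)
            else:
                dec = sorted(set(RNA_BASES) - set(rule.decision_bases))
                if not dec:
                    raise ValueError("nested rule leaves no bases for the else-class")
            mat[:, rule.decision_pos - 1] = [
                list(RNA_BASES).index(b) for b in rng.choice(dec, size=n)
            ]
        seqs.extend("".join(bases[row]) for row in mat)
        labels.extend([cls] * n)
    return seqs, labels


@dataclass(frozen=True)
class BulgeSpec:
    """A bulge planted in the duplex: ``length`` extra unpaired nucleotides
    on ``strand`` ('mature' or 'star') following mature position ``position``."""

    strand: str
    position: int
    length: int


def generate_hairpin(
    mature: str,
    mismatch_positions: Sequence[int] = (),
    wobble_positions: Sequence[int] = (),
    bulge: BulgeSpec | None = None,
    loop_length: int = 8,
    seed: int | np.random.Generator = 0,
    mirna_id: str = "syn-mir",
) -> MiRNARecord:
    """Build a hairpin precursor whose duplex deviates from perfect
    complementarity exactly at the requested mature positions.

    The duplex follows the canonical Dicer product geometry: mature
    positions 1..L-2 pair with the star arm and both strands carry 2-nt 3'
    overhangs.  Wobble positions require a G or U on the mature strand (the
    star partner becomes U or G); mismatch positions get a star partner that
    can neither Watson-Crick- nor wobble-pair.  A star-strand bulge inserts
    extra star nucleotides between two mature partners; a mature-strand
    bulge removes the star partners of the bulged mature positions.
    """
    mature = to_rna(mature)
    L = len(mature)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mism = set(mismatch_positions)
    wob = set(wobble_positions)
    if mism & wob:
        raise ValueError("mismatch and wobble positions overlap")
    pairable = L - 2  # 3' overhang positions never pair
    for pos in mism | wob:
        if not 1 <= pos <= pairable:
            raise ValueError(f"position {pos} outside pairable range 1..{pairable}")
    if bulge is not None:
        if bulge.strand not in ("mature", "star"):
            raise ValueError("bulge strand must be 'mature' or 'star'")
        if bulge.length < 1:
            raise ValueError("bulge length must be >= 1")
        bulged = (
            set(range(bulge.position + 1, bulge.position + 1 + bulge.length))
            if bulge.strand == "mature"
            else set()
        )
        if (bulged or {bulge.position}) & mism or (bulged or {bulge.position}) & wob:
            raise ValueError("bulge overlaps a mismatch/wobble position")

    def partner(i: int) -> str:  # i is a 1-based mature position
        m = mature[i - 1]
        if i in wob:
            if m not in _WOBBLE:
                raise ValueError(f"wobble at position {i} requires mature G or U, got {m}")
            return _WOBBLE[m]
        if i in mism:
            paired_with = {_WC[m]} | ({_WOBBLE[m]} if m in _WOBBLE else set())
            choices = sorted(set(RNA_BASES) - paired_with - {None})
            return str(rng.choice(choices))
        return _WC[m]

    # Star positions ascend 5'->3'; star index j pairs mature position L-2-j+1...
    # concretely the star partner of mature position i sits at star index (L-2) - i
    # (0-based), so we emit partners for mature positions L-2 down to 1.
    star_chars: list[str] = []
    for i in range(pairable, 0, -1):
        if bulge is not None and bulge.strand == "mature" and i in range(
            bulge.position + 1, bulge.position + 1 + bulge.length
        ):
            continue  # bulged-out mature base: no star partner
        if bulge is not None and bulge.strand == "star" and i == bulge.position:
            # Inserted bases must not pair with nearby mature bases, so the
            # planted bulge is the unique optimal alignment (contiguous gap).
            lo = max(1, bulge.position - bulge.length)
            hi = min(pairable, bulge.position + 1 + bulge.length)
            bad: set[str] = set()
            for m in mature[lo - 1 : hi]:
                bad.add(_WC[m])
                if m in _WOBBLE:
                    bad.add(_WOBBLE[m])
            choices = sorted(set(RNA_BASES) - bad) or sorted(
                set(RNA_BASES) - {_WC[mature[bulge.position - 1]], _WC[mature[bulge.position]]}
            )
            star_chars.extend(rng.choice(choices, size=bulge.length))
        star_chars.append(partner(i))
    overhang = "".join(rng.choice(list(RNA_BASES), size=2))
    star = "".join(star_chars) + overhang
    loop = "".join(rng.choice(list(RNA_BASES), size=loop_length))

    precursor = mature + loop + star
    rec = MiRNARecord(
        id=mirna_id,
        mature_seq=mature,
        precursor_seq=precursor,
        mature_start=1,
        mature_end=L,
        star_seq=star,
        star_start=L + loop_length + 1,
        star_end=L + loop_length + len(star),
    )
    rec.validate()
    return rec


def generate_reads(
    sequences: Sequence[str],
    labels: Sequence[str],
    lib: LibrarySpec | None = None,
    seed: int | np.random.Generator = 0,
    mirna_ids: Sequence[str] | None = None,
    adapter: str = DEFAULT_ADAPTER,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, list[str]], CountTable]:
    """Distribute reads for each miRNA over the AGO libraries.

    Per miRNA, an abundance weight is drawn log-normally and a library
    preference vector from a Dirichlet concentrated on the miRNA's true
    class; its reads are then multinomial over libraries.  Reads are the
    mature sequence with the 3' adapter appended and truncated to 30 nt.
    The returned :class:`CountTable` is the realized draw (noise reads
    enter the library totals but no count row).

    When ``out_dir`` is given, one 4-line FASTQ per library is also written
    (DNA alphabet, constant quality 'I').
    """
    if lib is None:
        lib = LibrarySpec()
    if len(sequences) != len(labels):
        raise ValueError("sequences and labels differ in length")
    unknown = set(labels) - set(lib.library_ids)
    if unknown:
        raise ValueError(f"labels without a library: {sorted(unknown)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mirna_ids is None:
        mirna_ids = [f"syn-mir-{i + 1}" for i in range(len(sequences))]

    libs = list(lib.library_ids)
    n_mir = len(sequences)
    total_signal = int(sum(lib.library_sizes[l] for l in libs) * (1 - lib.noise_fraction))
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=n_mir)
    per_mirna = rng.multinomial(total_signal, weights / weights.sum())

    counts = np.zeros((n_mir, len(libs)), dtype=np.int64)
    for i, cls in enumerate(labels):
        alpha = np.ones(len(libs))
        alpha[libs.index(cls)] = lib.preference_strength
        pref = rng.dirichlet(alpha)
        if np.isinf(lib.preference_strength):
            pref = np.zeros(len(libs))
            pref[libs.index(cls)] = 1.0
        counts[i] = rng.multinomial(per_mirna[i], pref)

    reads: dict[str, list[str]] = {l: [] for l in libs}
    for j, l in enumerate(libs):
        for i in range(n_mir):
            read = (sequences[i] + adapter)[:30]
            reads[l].extend([read] * counts[i, j])
        n_noise = int(round(lib.library_sizes[l] * lib.noise_fraction))
        for _ in range(n_noise):
            reads[l].append("".join(rng.choice(list(RNA_BASES), size=21)))
        perm = rng.permutation(len(reads[l]))
        reads[l] = [reads[l][k] for k in perm]

    table = CountTable(
        mirna_ids=list(mirna_ids),
        library_ids=libs,
        counts=counts,
        library_totals=np.array([max(1, len(reads[l])) for l in libs]),
        totals_provenance="given",
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for l in libs:
            with open(out / f"{l}.fastq", "w") as fh:
                for k, r in enumerate(reads[l]):
                    dna = r.replace("U", "T")
                    fh.write(f"@{l}_read{k + 1}\n{dna}\n+\n{'I' * len(dna)}\n")
    return reads, table


def truth_manifest(
    sequences: Sequence[str],
    labels: Sequence[str],
    spec: SignalSpec,
    mirna_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Ground-truth table for a generated cohort: one row per sequence with
    its label, plus the planted signal positions and rule definitions."""
    if mirna_ids is None:
        mirna_ids = [f"syn-mir-{i + 1}" for i in range(len(sequences))]
    signal_positions = ",".join(str(p) for p in sorted(spec.position_signals)) or "none"
    rules = (
        ";".join(
            f"pos{r.condition_pos}in{''.join(sorted(r.condition_bases))}:"
            f"pos{r.decision_pos}in{''.join(sorted(r.decision_bases))}"
            f"->{r.class_if_true}else{r.class_if_false}"
            for r in spec.nested_rules
        )
        or "none"
    )
    return pd.DataFrame(
        {
            "mirna_id": list(mirna_ids),
            "sequence": list(sequences),
            "label": list(labels),
            "signal_positions": signal_positions,
            "nested_rules": rules,
        }
    )
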