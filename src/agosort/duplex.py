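"""miRNA:miRNA* duplex pairing patterns and the precursor quality filter.

The mature and star arms of a hairpin precursor pair antiparallel, each
with a 2-nt 3' overhang.  After removing the overhangs, the two strands are
globally aligned under a deterministic pairing score (Watson-Crick +2, G:U
wobble +1, other aligned pair -1, gap -2) and every mature position is
classified as WC, wobble, or unpaired.  Externally computed duplex
structures can be supplied as state strings instead, so the built-in
aligner is swappable.

Precursors with more than six mismatches or a bulge longer than three
nucleotides in the duplex are considered spurious annotations and fail the
filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .io import WC_PAIRS, WOBBLE_PAIRS, MiRNARecord

logger = logging.getLogger("agosort")

WC, WOBBLE, UNPAIRED = "WC", "wobble", "unpaired"
_STATE_CHAR = {WC: "W", WOBBLE: "w", UNPAIRED: "U"}
_CHAR_STATE = {v: k for k, v in _STATE_CHAR.items()}
_CHAR_STATE["."] = UNPAIRED

MATCH_WC = 2.0
MATCH_WOBBLE = 1.0
MISMATCH = -1.0
GAP = -2.0


@dataclass
class DuplexPattern:
    """Per-position pairing states of a mature miRNA within its duplex.

    ``states[i]`` describes mature position i+1 (after 3'-overhang
    removal).  ``n_mismatches`` counts aligned but non-pairing columns;
    symmetric internal loops therefore count once per mature position
    involved.  ``max_bulge`` is the longest gap run on either strand.
    """

    states: list[str]
    n_mismatches: int
    max_bulge: int
    score: float = 0.0

    def to_string(self) -> str:
        return "".join(_STATE_CHAR[s] for s in self.states)

    @classmethod
    def from_string(cls, s: str, n_mismatches: int | None = None, max_bulge: int = 0) -> "DuplexPattern":
        states = [_CHAR_STATE[c] for c in s]
        if n_mismatches is None:
            n_mismatches = sum(1 for st in states if st == UNPAIRED)
        return cls(states=states, n_mismatches=n_mismatches, max_bulge=max_bulge)


def _pair_score(a: str, b: str) -> float:
    if (a, b) in WC_PAIRS:
        return MATCH_WC
    if (a, b) in WOBBLE_PAIRS:
        return MATCH_WOBBLE
    return MISMATCH


def _align(a: str, b: str) -> tuple[float, list[tuple[int, int]]]:
    """Global alignment of a (mature) against b (star, 3'->5').

    Returns the score and the list of moves as (di, dj): (1,1) aligned
    column, (1,0) gap in star (mature bulge), (0,1) gap in mature (star
    bulge).  Score ties prefer fewer gaps, then aligned columns earliest
    (leftmost gap placement).
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    # score[i][j], gaps[i][j] for prefixes a[:i], b[:j]; lexicographic max on
    # (score, -gaps).
    score = [[NEG] * (m + 1) for _ in range(n + 1)]
    gaps = [[0] * (m + 1) for _ in range(n + 1)]
    move = [[0] * (m + 1) for _ in range(n + 1)]  # 1 diag, 2 up (gap in b), 3 left (gap in a)
    score[0][0] = 0.0
    for i in range(1, n + 1):
        score[i][0] = i * GAP
        gaps[i][0] = i
        move[i][0] = 2
    for j in range(1, m + 1):
        score[0][j] = j * GAP
        gaps[0][j] = j
        move[0][j] = 3
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            cand = (
                (score[i - 1][j - 1] + _pair_score(ai, b[j - 1]), gaps[i - 1][j - 1], 1),
                (score[i - 1][j] + GAP, gaps[i - 1][j] + 1, 2),
                (score[i][j - 1] + GAP, gaps[i][j - 1] + 1, 3),
            )
            best = max(cand, key=lambda t: (t[0], -t[1], -t[2]))
            score[i][j], gaps[i][j], move[i][j] = best
    moves: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i][j]
        if mv == 1:
            moves.append((1, 1))
            i, j = i - 1, j - 1
        elif mv == 2:
            moves.append((1, 0))
            i -= 1
        else:
            moves.append((0, 1))
            j -= 1
    moves.reverse()
    return score[n][m], moves


def infer_duplex(record: MiRNARecord, overhang: int = 2) -> DuplexPattern:
    """Infer the pairing pattern of a mature miRNA against its star strand.

    The star sequence is taken from the record, or sliced from the
    precursor via the star coordinates.  ``overhang`` nucleotides are
    removed from the 3' end of both strands before alignment (the canonical
    2-nt Dicer overhangs, which never pair).
    """
    star = record.star_seq
    if star is None:
        if record.star_start is None or record.star_end is None:
            raise ValueError(f"{record.id}: no star sequence and no star coordinates")
        star = record.precursor_seq[record.star_start - 1 : record.star_end]
    mature_t = record.mature_seq[: len(record.mature_seq) - overhang]
    star_t = star[: len(star) - overhang]
    # Antiparallel pairing: the star partner of the mature 5' end lies at the
    # star 3' side, so the star strand is reversed before alignment.
    _score, moves = _align(mature_t, star_t[::-1])

    states: list[str] = []
    n_mismatch = 0
    max_bulge = 0
    run_a = run_b = 0
    pos_a = pos_b = 0
    star_rev = star_t[::-1]
    for di, dj in moves:
        if di == 1 and dj == 1:
            a, b = mature_t[pos_a], star_rev[pos_b]
            if (a, b) in WC_PAIRS:
                states.append(WC)
            elif (a, b) in WOBBLE_PAIRS:
                states.append(WOBBLE)
            else:
                states.append(UNPAIRED)
                n_mismatch += 1
            run_a = run_b = 0
            pos_a += 1
            pos_b += 1
        elif di == 1:  # gap in star: mature base bulged out
            states.append(UNPAIRED)
            run_a += 1
            run_b = 0
            max_bulge = max(max_bulge, run_a)
            pos_a += 1
        else:  # gap in mature: star base bulged out
            run_b += 1
            run_a = 0
            max_bulge = max(max_bulge, run_b)
            pos_b += 1
    return DuplexPattern(states=states, n_mismatches=n_mismatch, max_bulge=max_bulge, score=_score)


def filter_precursor(
    pattern: DuplexPattern, max_mismatches: int = 6, max_bulge: int = 3
) -> tuple[bool, str | None]:
    """Quality filter on the duplex: fail on > max_mismatches mismatches or
    a bulge longer than max_bulge nucleotides (both strict inequalities)."""
    if pattern.n_mismatches > max_mismatches:
        return False, "mismatches"
    if pattern.max_bulge > max_bulge:
        return False, "bulge"
    return True, None


def pairing_frequency_profile(
    patterns_by_class: Mapping[str, Sequence[DuplexPattern]],
    max_position: int = 19,
) -> pd.DataFrame:
    """Percent of duplexes paired (WC or wobble) per mature position and class.

    Positions run 1..max_position; the default 19 stops short of the 2-nt
    3' overhang of a 21-mer, beyond which pairing is undefined.  Patterns
    shorter than ``max_position`` count as unpaired at the missing
    positions.  A "Total" column pools all classes (union, not the mean of
    the class profiles).
    """
    for cls, patterns in patterns_by_class.items():
        if len(patterns) == 0:
            raise ValueError(f"class {cls} has no duplex patterns")

    def pct_paired(patterns: Sequence[DuplexPattern], pos: int) -> float:
        paired = sum(
            1
            for p in patterns
            if pos <= len(p.states) and p.states[pos - 1] in (WC, WOBBLE)
        )
        return paired / len(patterns) * 100.0

    pooled = [p for patterns in patterns_by_class.values() for p in patterns]
    data = {"position": list(range(1, max_position + 1))}
    for cls, patterns in patterns_by_class.items():
        data[cls] = [pct_paired(patterns, pos) for pos in data["position"]]
    data["Total"] = [pct_paired(pooled, pos) for pos in data["position"]]
    return pd.DataFrame(data)


def patterns_to_frame(patterns: Mapping[str, DuplexPattern]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna_id": list(patterns),
            "states": [p.to_string() for p in patterns.values()],
            "n_mismatches": [p.n_mismatches for p in patterns.values()],
            "max_bulge": [p.max_bulge for p in patterns.values()],
            "score": [p.score for p in patterns.values()],
        }
    )


def read_patterns_tsv(path: str | Path) -> dict[str, DuplexPattern]:
    """Import externally computed duplex patterns from a state-string TSV."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, DuplexPattern] = {}
    for row in df.itertuples():
        out[str(row.mirna_id)] = DuplexPattern.from_string(
            str(row.states),
            n_mismatches=int(row.n_mismatches) if "n_mismatches" in df.columns else None,
            max_bulge=int(row.max_bulge) if "max_bulge" in df.columns else 0,
        )
    return out
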