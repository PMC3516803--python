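"""Univariate positional statistics for AGO sorting signals.

The central quantity is the mutual information (in bits) between the AGO
class vector and the base occupying one column of the 5'-anchored,
ungapped alignment of 21-mer mature sequences:

    MI = sum_{ago,base} P(ago,base) * log2( P(ago,base) / (P(ago) P(base)) )

with empirical probabilities and zero-probability cells contributing
nothing.  Significance comes from an empirical permutation null (label
shuffling per position, which preserves each column's base composition),
adjusted across the 21 positions by Benjamini-Hochberg.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .confidence import ConfidenceSet
from .io import RNA_BASES

_BASE_CODE = {b: i for i, b in enumerate(RNA_BASES)}


def _mi_from_counts(counts: np.ndarray) -> np.ndarray:
    """MI in bits from joint count tables; counts has shape (..., K, B)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=(-2, -1), keepdims=True)
    if np.any(n == 0):
        raise ValueError("empty joint count table")
    p = counts / n
    pr = p.sum(axis=-1, keepdims=True)
    pc = p.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log2(p / (pr * pc))
    term = np.where(p > 0, term, 0.0)
    return term.sum(axis=(-2, -1))


def _encode(values: Sequence) -> tuple[np.ndarray, int]:
    uniq = sorted(set(values))
    code = {v: i for i, v in enumerate(uniq)}
    return np.array([code[v] for v in values]), len(uniq)


def mutual_information(labels: Sequence, bases: Sequence) -> float:
    """Empirical mutual information in bits between two categorical vectors."""
    if len(labels) != len(bases):
        raise ValueError("labels and bases differ in length")
    if len(labels) == 0:
        raise ValueError("empty input")
    y, k = _encode(labels)
    x, b = _encode(bases)
    counts = np.bincount(y * b + x, minlength=k * b).reshape(k, b)
    return float(_mi_from_counts(counts))


def permutation_pvalue(
    labels: Sequence,
    bases: Sequence,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, dict[str, float]]:
    """Empirical p-value of the observed MI under label shuffling.

    Uses the add-one convention p = (1 + #{MI_null >= MI_obs}) / (n_perm+1),
    so p is never exactly zero.  Ties count as exceedances: a constant
    column has MI 0 under every shuffle and p = 1.  Returns the p-value and
    a null summary (5th percentile, mean, 95th percentile).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y, k = _encode(labels)
    x, b = _encode(bases)
    n = len(y)
    obs = float(_mi_from_counts(np.bincount(y * b + x, minlength=k * b).reshape(k, b)))
    perms = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
    idx = perms * b + x[None, :]
    offset = np.arange(n_perm)[:, None] * (k * b)
    flat = (idx + offset).ravel()
    null_counts = np.bincount(flat, minlength=n_perm * k * b).reshape(n_perm, k, b)
    null_mi = _mi_from_counts(null_counts)
    p_emp = (1 + int(np.sum(null_mi >= obs - 1e-12))) / (n_perm + 1)
    summary = {
        "null_q05": float(np.quantile(null_mi, 0.05)),
        "null_mean": float(null_mi.mean()),
        "null_q95": float(np.quantile(null_mi, 0.95)),
    }
    return p_emp, summary


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mi_profile(
    data: ConfidenceSet | tuple[Sequence[str], Sequence[str]],
    class_subset: Sequence[str] | None = None,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
    n_positions: int | None = None,
) -> pd.DataFrame:
    """Per-position MI profile with permutation p-values and BH-FDR.

    ``data`` is either a confidence set (its 21-mer view is used) or a
    (sequences, labels) pair of equal-length, 5'-aligned, ungapped
    sequences — the latter form serves star-strand and synthetic input.
    The label vector is shuffled independently per position, preserving
    each column's base composition.  FDR is applied across the profile's
    positions.
    """
    if isinstance(data, ConfidenceSet):
        seqs, labels = data.aligned21()
    else:
        seqs, labels = list(data[0]), list(data[1])
    if class_subset is not None:
        for cls in class_subset:
            if cls not in labels:
                raise ValueError(f"class {cls} has no members")
        keep = [i for i, lab in enumerate(labels) if lab in set(class_subset)]
        seqs = [seqs[i] for i in keep]
        labels = [labels[i] for i in keep]
    if len(set(labels)) < 2:
        raise ValueError("need at least two classes")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must be equal-length and ungapped")
    length = lengths.pop()
    if n_positions is None:
        n_positions = length
    if n_positions > length:
        raise ValueError("more positions requested than sequence length")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for pos in range(1, n_positions + 1):
        column = [s[pos - 1] for s in seqs]
        bad = set(column) - set(RNA_BASES)
        if bad:
            raise ValueError(f"position {pos}: non-ACGU characters {sorted(bad)}")
        mi = mutual_information(labels, column)
        p_emp, summary = permutation_pvalue(labels, column, n_perm=n_perm, seed=rng)
        rows.append({"position": pos, "mi_bits": mi, **summary, "p_emp": p_emp})
    df = pd.DataFrame(rows)
    df["p_fdr"] = bh_fdr(df["p_emp"].to_numpy())
    return df


def composition_from_counts(
    class_counts: Mapping[str, Mapping[str, int]],
    background_counts: Mapping[str, int],
) -> pd.DataFrame:
    """5'-base composition table with enrichment ratios vs. background.

    The enrichment ratio is the class base frequency divided by the
    background base frequency (a relative enrichment); classes with a zero
    count get ratio 0, and a nonzero count over a zero background frequency
    is flagged infinite.
    """
    bg_total = sum(background_counts.values())
    if bg_total <= 0:
        raise ValueError("empty background")
    rows = []
    for cls in class_counts:
        class_size = sum(class_counts[cls].values())
        for base in RNA_BASES:
            count = class_counts[cls].get(base, 0)
            bg = background_counts.get(base, 0)
            if count == 0:
                ratio = 0.0
            elif bg == 0:
                ratio = float("inf")
            else:
                ratio = (count / class_size) / (bg / bg_total)
            rows.append(
                {
                    "ago_class": cls,
                    "base": base,
                    "count": count,
                    "class_size": class_size,
                    "background_count": bg,
                    "enrichment_ratio": ratio,
                }
            )
    return pd.DataFrame(rows)


def base_composition(
    cset: ConfidenceSet, background_counts: Mapping[str, int]
) -> pd.DataFrame:
    """5'-base composition of a confidence set against a background of all
    known miRNAs (counts of 5' bases over the full miRNA complement)."""
    class_counts: dict[str, dict[str, int]] = {}
    for e in cset.entries:
        d = class_counts.setdefault(e.ago_label, {})
        first = e.full_seq[0]
        d[first] = d.get(first, 0) + 1
    return composition_from_counts(class_counts, background_counts)


def logo_information(
    seqs: Sequence[str] | ConfidenceSet,
    small_sample_correction: bool = False,
) -> pd.DataFrame:
    """Sequence-logo information content per position of aligned sequences.

    R_i = 2 - H_i bits, optionally minus the small-sample correction
    e_n = 3 / (2 n ln 2), floored at zero; per-base letter heights are
    frequency x R_i.  Two bits means a position occupied by a single base.
    """
    if isinstance(seqs, ConfidenceSet):
        seqs = seqs.aligned21()[0]
    if len(seqs) == 0:
        raise ValueError("no sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned (equal length)")
    n = len(seqs)
    length = lengths.pop()
    e_n = 3.0 / (2.0 * np.log(2) * n) if small_sample_correction else 0.0
    rows = []
    for pos in range(1, length + 1):
        column = [s[pos - 1] for s in seqs]
        freqs = np.array([column.count(b) / n for b in RNA_BASES])
        nz = freqs[freqs > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        info = max(0.0, 2.0 - entropy - e_n)
        row = {"position": pos, "info_bits": info}
        for b, f in zip(RNA_BASES, freqs):
            row[f"height_{b}"] = f * info
        rows.append(row)
    return pd.DataFrame(rows)


def correlate_profiles(
    x_profile: Sequence[float], y_profile: Sequence[float]
) -> dict[str, float]:
    """Pearson and Spearman correlation between two positional profiles,
    e.g. an MI profile versus per-position protein-RNA hydrogen-bond counts."""
    x = np.asarray(x_profile, dtype=float)
    y = np.asarray(y_profile, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance profile")
    pear = sps.pearsonr(x, y)
    spear = sps.spearmanr(x, y)
    return {
        "pearson_r": float(pear.statistic),
        "pearson_p": float(pear.pvalue),
        "spearman_rho": float(spear.statistic),
        "spearman_p": float(spear.pvalue),
    }
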