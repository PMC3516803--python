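"""End-to-end orchestration: synthetic data -> counting -> confidence set
-> positional statistics -> duplex profiles -> forest comparisons.

Each stage is also exposed individually through the command-line interface;
this module wires them together and writes one TSV per result table plus a
JSON run manifest, so a run is fully reproducible from its config and seed.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import confidence as conf
from . import duplex as dpx
from . import forest as rf
from . import simulate as sim
from . import stats as pstats
from .io import MiRNARecord, RunConfig, write_report

logger = logging.getLogger("agosort")

RF_CLASSES = ("AGO1", "AGO2", "AGO5")


def synthesize_cohort(
    spec: sim.SignalSpec,
    lib: sim.LibrarySpec,
    seed: int,
    fastq_dir: str | Path | None = None,
) -> dict:
    """Generate sequences, hairpin precursors, and co-IP read libraries.

    Most hairpins carry a few scattered wobbles and mismatches (drawn per
    record); a small fraction get a long bulge or an excess of mismatches so
    the precursor quality filter always has work to do.
    """
    rng = np.random.default_rng(seed)
    sequences, labels = sim.generate_sequences(spec, length=21, seed=rng)
    ids = [f"syn-mir-{i + 1}" for i in range(len(sequences))]

    records: list[MiRNARecord] = []
    pairable = 21 - 2
    for mid, seq in zip(ids, sequences):
        defect = rng.random()
        positions = list(rng.permutation(np.arange(2, pairable + 1)))
        wob = [int(p) for p in positions if seq[p - 1] in "GU"][: int(rng.integers(0, 3))]
        remaining = [int(p) for p in positions if p not in wob]
        if defect < 0.03:
            mism = remaining[:8]  # spuriously annotated: fails the mismatch rule
            bulge = None
        elif defect < 0.06:
            mism = remaining[: int(rng.integers(0, 3))]
            free = [p for p in remaining if p not in mism and 2 <= p <= pairable - 1]
            bulge = sim.BulgeSpec(strand="star", position=free[0], length=int(rng.integers(4, 7)))
        else:
            mism = remaining[: int(rng.integers(0, 3))]
            bulge = None
        records.append(
            sim.generate_hairpin(
                seq,
                mismatch_positions=mism,
                wobble_positions=wob,
                bulge=bulge,
                seed=rng,
                mirna_id=mid,
            )
        )

    reads, truth_table = sim.generate_reads(
        sequences, labels, lib=lib, seed=rng, mirna_ids=ids, out_dir=fastq_dir
    )
    return {
        "sequences": sequences,
        "labels": labels,
        "ids": ids,
        "records": records,
        "reads": reads,
        "truth_table": truth_table,
        "truth_manifest": sim.truth_manifest(sequences, labels, spec, ids),
    }


def star_columns(
    records_by_id: Mapping[str, MiRNARecord],
    cset: conf.ConfidenceSet,
    anchor: str = "opposite",
) -> tuple[list[str], list[str]]:
    """Star-strand columns for MI analysis.

    ``anchor='opposite'`` aligns star bases by the mature position they sit
    opposite to in the duplex (column i is the star base opposite mature
    position i); ``anchor='star5p'`` left-aligns the star strands on their
    own 5' terminus.  Sequences are cropped to the shortest member so the
    matrix is rectangular.
    """
    seqs: list[str] = []
    labels: list[str] = []
    for e in cset.entries:
        rec = records_by_id.get(e.id)
        if rec is None or rec.star_seq is None:
            continue
        star = rec.star_seq
        if anchor == "star5p":
            s = star
        elif anchor == "opposite":
            # The star 3' overhang (2 nt) sits past the mature 5' end; the
            # base opposite mature position i is star[len-2-i] (1-based i).
            s = star[::-1][2:]
        else:
            raise ValueError(f"unknown star anchor {anchor!r}")
        seqs.append(s)
        labels.append(e.ago_label)
    if not seqs:
        raise ValueError("no star sequences available")
    min_len = min(len(s) for s in seqs)
    return [s[:min_len] for s in seqs], labels


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    spec: sim.SignalSpec | None = None,
    lib: sim.LibrarySpec | None = None,
    hbond_profile: Sequence[float] | None = None,
    write_fastq: bool = False,
) -> dict:
    """Run the full synthetic analysis and write all result tables.

    Returns a dictionary with the manifest and the in-memory stage results
    (confidence set, profiles, forest reports).  A stage failure aborts
    with the stage name after writing the tables produced so far.
    """
    out_dir = Path(out_dir)
    spec = spec if spec is not None else sim.table1_signal_spec()
    lib = lib if lib is not None else sim.LibrarySpec(library_ids=tuple(spec.class_names))
    results: dict[str, pd.DataFrame] = {}
    stage = "init"
    try:
        stage = "simulate"
        cohort = synthesize_cohort(
            spec, lib, seed=config.seed, fastq_dir=out_dir / "fastq" if write_fastq else None
        )
        records_by_id = {r.id: r for r in cohort["records"]}
        results["truth"] = cohort["truth_manifest"]
        results["counts_true"] = cohort["truth_table"].to_frame().reset_index(names="mirna_id")

        stage = "count"
        table = conf.count_reads(cohort["reads"], cohort["records"])
        results["counts"] = table.to_frame().reset_index(names="mirna_id")
        rpm = conf.normalize_rpm(table)
        results["rpm"] = rpm.to_frame().reset_index(names="mirna_id")

        stage = "preference"
        assignments = conf.assign_preference(
            rpm, min_rpm=config.min_rpm, threshold=config.preference_fraction
        )
        results["assignments"] = assignments

        stage = "duplex"
        patterns = {r.id: dpx.infer_duplex(r) for r in cohort["records"]}
        verdicts = {
            mid: dpx.filter_precursor(p, config.max_mismatches, config.max_bulge)
            for mid, p in patterns.items()
        }
        results["duplex_patterns"] = dpx.patterns_to_frame(patterns)

        stage = "confidence_set"
        cset = conf.build_confidence_set(assignments, cohort["records"], verdicts)
        results["confidence_set"] = cset.to_frame()
        cset3 = cset.subset(RF_CLASSES)

        stage = "mi"
        seed_mi = config.seed + 1
        results["mi_three_class"] = pstats.mi_profile(
            cset3, n_perm=config.n_perm, seed=seed_mi
        )
        results["mi_ago1_ago5"] = pstats.mi_profile(
            cset3, class_subset=("AGO1", "AGO5"), n_perm=config.n_perm, seed=seed_mi + 1
        )
        star_data = star_columns(records_by_id, cset3, anchor="opposite")
        results["mi_star"] = pstats.mi_profile(
            star_data, n_perm=config.n_perm, seed=seed_mi + 2
        )

        stage = "composition"
        background = {b: 0 for b in "ACGU"}
        for s in cohort["sequences"]:
            background[s[0]] += 1
        results["composition"] = pstats.base_composition(cset, background)

        stage = "logo"
        logos = []
        for cls in RF_CLASSES:
            sub = cset3.subset([cls])
            if sub.entries:
                df = pstats.logo_information(sub)
                df.insert(0, "ago_class", cls)
                logos.append(df)
        results["logo_matrix"] = pd.concat(logos, ignore_index=True)

        stage = "pairing_profile"
        by_class: dict[str, list[dpx.DuplexPattern]] = {}
        for e in cset3.entries:
            if e.id in patterns:
                by_class.setdefault(e.ago_label, []).append(patterns[e.id])
        results["pairing_profile"] = dpx.pairing_frequency_profile(by_class)

        stage = "rf"
        seqs3_labels = [e.ago_label for e in cset3.entries]
        f_all = rf.encode_features(cset3, mode="sequence")
        f_nofirst = rf.encode_features(cset3, mode="sequence", include_first=False)
        f_first = rf.first_position_only(f_all)
        pat3 = {e.id: patterns[e.id] for e in cset3.entries}
        f_pair = rf.encode_features(cset3, mode="pairing", patterns=pat3)

        rng_rf = np.random.default_rng(config.seed + 101)
        shuffled = [seqs3_labels[i] for i in rng_rf.permutation(len(seqs3_labels))]
        conditions = {
            "A_class_shuffled": (f_all, shuffled),
            "B_seq_no_first": (f_nofirst, seqs3_labels),
            "C_first_only": (f_first, seqs3_labels),
            "D_seq_all": (f_all, seqs3_labels),
            "E_pairing": (f_pair, seqs3_labels),
        }
        rf_rows = []
        forests = {}
        for name, (feats, labs) in conditions.items():
            res = rf.train_forest(
                feats, labs, n_trees=config.n_trees, sampsize=config.sampsize,
                seed=config.seed + 7,
            )
            forests[name] = res
            rf_rows.append(
                {
                    "condition": name,
                    "oob_accuracy": res.oob_accuracy,
                    "mean_margin": float(np.mean(rf.margins(res, labs))),
                    "n_trees": config.n_trees,
                    "sampsize": config.sampsize,
                }
            )
        results["rf_report"] = pd.DataFrame(rf_rows)

        imp = rf.variable_importance(
            forests["D_seq_all"], f_all, seqs3_labels, seed=config.seed + 8
        )
        results["importance"] = pd.DataFrame(
            {"position": f_all.positions, "mean_decrease_accuracy": imp}
        )

        stage = "comparisons"
        comparisons = []
        for label, (fa, fb, shuffle) in {
            "B_vs_A": (f_nofirst, f_all, "b"),
            "D_vs_C": (f_all, f_first, None),
            "E_vs_E_shuffled": (f_pair, f_pair, "b"),
        }.items():
            cmp_res = rf.compare_conditions(
                fa, fb, seqs3_labels, n_runs=config.n_runs, seed=config.seed + 9,
                shuffle=shuffle, n_trees=config.n_trees, sampsize=config.sampsize,
            )
            comparisons.append(
                {
                    "comparison": label,
                    "median_p": cmp_res["median_p"],
                    "mean_acc_a": cmp_res["mean_acc_a"],
                    "mean_acc_b": cmp_res["mean_acc_b"],
                    "n_runs": cmp_res["n_runs"],
                }
            )
        results["comparisons"] = pd.DataFrame(comparisons)

        if hbond_profile is not None:
            stage = "structure_correlation"
            mi_vals = results["mi_three_class"]["mi_bits"].to_numpy()[: len(hbond_profile)]
            corr = pstats.correlate_profiles(mi_vals, list(hbond_profile))
            results["structure_correlation"] = pd.DataFrame([corr])

        stage = "report"
        manifest = write_report(
            results,
            out_dir,
            config=config,
            seed=config.seed,
            extra={"class_counts": cset.class_counts, "stages": "complete"},
        )
    except Exception as err:
        write_report(results, out_dir, config=config, seed=config.seed,
                     extra={"stages": f"failed at {stage}"})
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    return {
        "manifest": manifest,
        "results": results,
        "confidence_set": cset,
        "records": cohort["records"],
        "truth": cohort["truth_manifest"],
    }
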