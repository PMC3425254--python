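"""Text-table readers and writers for every pipeline artifact.

All tables are tab-separated with a header line; matrices are written
samples x probes with a ``sample_id`` first column.  The per-sample/per-
probe intensity export follows the GenomeStudio "Final Report" layout
(one row per sample x probe with ``Sample ID / SNP Name / Chr / Position /
X / Y`` columns, optionally precomputed ``Log R Ratio`` / ``B Allele
Freq`` columns instead of raw channels).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .simulate import Cohort, ProbeDef, RawIntensities

FINAL_REPORT_COLUMNS = ["Sample ID", "SNP Name", "Chr", "Position", "X", "Y"]
PRECOMPUTED_COLUMNS = ["Log R Ratio", "B Allele Freq"]
FLOAT_FORMAT = "%.6g"


def write_final_report(path, cohort: Cohort, raw: RawIntensities,
                       probes: list) -> None:
    n, m = raw.X.shape
    df = pd.DataFrame(
        {
            "Sample ID": np.repeat(cohort.sample_id, m),
            "SNP Name": np.tile([p.probe_id for p in probes], n),
            "Chr": np.tile([p.chromosome for p in probes], n),
            "Position": np.tile([p.position for p in probes], n),
            "X": raw.X.ravel(),
            "Y": raw.Y.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_final_report(path):
    """Read a Final-Report-like TSV.

    Returns ``(sample_ids, probe_table, X, Y, lrr, baf)`` where either the
    (X, Y) pair or the (lrr, baf) pair is None, depending on whether the
    file carries raw channels or precomputed signal columns.  Missing
    required columns and duplicated sample x probe rows are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ["Sample ID", "SNP Name", "Chr", "Position"]:
        if col not in df.columns:
            raise ValueError(f"final report is missing column {col!r}")
    has_raw = all(c in df.columns for c in ["X", "Y"])
    has_pre = all(c in df.columns for c in PRECOMPUTED_COLUMNS)
    if not (has_raw or has_pre):
        raise ValueError(
            "final report needs either 'X'/'Y' or "
            "'Log R Ratio'/'B Allele Freq' columns"
        )
    if df.duplicated(subset=["Sample ID", "SNP Name"]).any():
        dup = df[df.duplicated(subset=["Sample ID", "SNP Name"])].iloc[0]
        raise ValueError(
            f"duplicated sample x probe row: {dup['Sample ID']} / "
            f"{dup['SNP Name']}"
        )
    probe_table = (
        df[["SNP Name", "Chr", "Position"]]
        .drop_duplicates("SNP Name")
        .sort_values(["Chr", "Position"], kind="stable")
        .reset_index(drop=True)
    )
    sample_ids = list(pd.unique(df["Sample ID"]))
    order = probe_table["SNP Name"].tolist()

    def pivot(col):
        mat = df.pivot(index="Sample ID", columns="SNP Name", values=col)
        return mat.loc[sample_ids, order].to_numpy(dtype=float)

    if has_pre:
        return sample_ids, probe_table, None, None, \
            pivot("Log R Ratio"), pivot("B Allele Freq")
    return sample_ids, probe_table, pivot("X"), pivot("Y"), None, None


def probes_from_table(probe_table: pd.DataFrame, locus_ids=None) -> list:
    locus_ids = set(locus_ids or [])
    return [
        ProbeDef(
            probe_id=row["SNP Name"],
            chromosome=str(row["Chr"]),
            position=int(row["Position"]),
            is_locus_probe=row["SNP Name"] in locus_ids,
        )
        for _, row in probe_table.iterrows()
    ]


def write_sample_sheet(path, cohort: Cohort) -> None:
    df = cohort.covariates.copy()
    df.insert(0, "sample_id", cohort.sample_id)
    df.insert(
        1, "status",
        np.where(cohort.phenotype == 1, "case", "control"),
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ["sample_id", "status"]:
        if col not in df.columns:
            raise ValueError(f"sample sheet is missing column {col!r}")
    bad = set(df["status"]) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown status values: {sorted(bad)}")
    return df


def write_truth(path, cohort: Cohort) -> None:
    pd.DataFrame(
        {"sample_id": cohort.sample_id,
         "copy_number": cohort.true_copy_number}
    ).to_csv(path, sep="\t", index=False)


def write_matrix(path, mat, sample_ids, probe_ids) -> None:
    df = pd.DataFrame(np.atleast_2d(mat), columns=probe_ids)
    df.insert(0, "sample_id", sample_ids)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_matrix(path):
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("matrix file is missing column 'sample_id'")
    sample_ids = df["sample_id"].tolist()
    probe_ids = [c for c in df.columns if c != "sample_id"]
    return sample_ids, probe_ids, df[probe_ids].to_numpy(dtype=float)


def write_cluster_model(path, model, probe_ids=None) -> None:
    rows = []
    for pc in model.probes:
        for t, c, r in zip(pc.theta_centers, pc.canonical, pc.r_expected):
            rows.append(
                {"probe_id": pc.probe_id, "mode": model.mode,
                 "theta_center": t, "canonical_baf": c, "r_expected": r}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format=FLOAT_FORMAT)


def write_calls_bed(path, calls_by_sample, probes) -> None:
    """BED-like calls: 0-based half-open intervals from 1-based positions."""
    rows = []
    for sid, calls in calls_by_sample.items():
        for c in calls:
            rows.append(
                {
                    "chrom": probes[c.start_index].chromosome,
                    "start": c.start_position - 1,
                    "end": c.end_position,
                    "sample_id": sid,
                    "copy_number": c.copy_number,
                }
            )
    cols = ["chrom", "start", "end", "sample_id", "copy_number"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_paths(path, paths, probes) -> None:
    mat = np.vstack([p.states for p in paths])
    write_matrix(path, mat, [p.sample_id for p in paths],
                 [p.probe_id for p in probes])


def association_table(results, mixture=None, n_cases=0,
                      n_controls=0) -> pd.DataFrame:
    """One row per test, Table-1-like layout."""
    rows = []
    for r in results:
        rows.append(
            {
                "predictor": r.predictor,
                "n_controls": r.n_controls,
                "n_cases": r.n_cases,
                "OR": r.odds_ratio,
                "CI_low": r.ci_low,
                "CI_high": r.ci_high,
                "p_value": r.p_value,
                "method": r.method,
            }
        )
    if mixture is not None:
        rows.append(
            {
                "predictor": "mixture",
                "n_controls": n_controls,
                "n_cases": n_cases,
                "OR": mixture.odds_ratio,
                "CI_low": mixture.ci_low,
                "CI_high": mixture.ci_high,
                "p_value": mixture.p_value,
                "method": "joint_mixture",
            }
        )
    return pd.DataFrame(rows)


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return path
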