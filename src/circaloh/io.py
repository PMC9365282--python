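"""Readers and writers for the tool's on-disk formats.

Conventions: traces and plates are CSV; expression, clinical, depth and
all report tables are TSV with header rows; intervals use BED-style
0-based half-open coordinates; missing values are written as "NA";
gene sets come as plain lists (one symbol per line) or GMT.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .covsurv import CohortBundle
from .dpcr import PartitionPlate
from .loh import DepthTrackSet
from .rhythm import Trace

NA = "NA"

__all__ = [
    "write_traces_csv", "read_traces_csv",
    "write_plates_csv", "read_plates_csv",
    "write_expression_tsv", "read_expression_tsv",
    "write_clinical_tsv", "read_clinical_tsv",
    "write_depth_tsv", "read_depth_tsv",
    "write_groups_tsv", "read_groups_tsv",
    "read_gene_list", "read_gmt", "read_gene_set",
    "write_table", "load_config", "sha256_of",
]


def write_traces_csv(traces, path) -> None:
    frames = [pd.DataFrame({
        "sample_id": tr.sample_id, "patient_id": tr.patient_id,
        "condition": tr.condition, "time_h": tr.times, "signal": tr.values,
    }) for tr in traces]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path) -> list[Trace]:
    df = pd.read_csv(path)
    traces = []
    for sid, sub in df.groupby("sample_id", sort=False):
        sub = sub.sort_values("time_h")
        traces.append(Trace(
            sample_id=str(sid),
            times=sub["time_h"].to_numpy(dtype=float),
            values=sub["signal"].to_numpy(dtype=float),
            patient_id=str(sub["patient_id"].iloc[0]) if "patient_id" in sub else "",
            condition=str(sub["condition"].iloc[0]) if "condition" in sub else "",
        ))
    return traces


def write_plates_csv(plates, path) -> None:
    pd.DataFrame([{
        "sample_id": p.sample_id, "n_partitions": p.n_partitions,
        "target_positive": p.target_positive,
        "reference_positive": p.reference_positive,
        "true_cnv": p.true_cnv if p.true_cnv is not None else NA,
    } for p in plates]).to_csv(path, index=False)


def read_plates_csv(path) -> list[PartitionPlate]:
    df = pd.read_csv(path, na_values=[NA])
    return [PartitionPlate(
        n_partitions=int(r.n_partitions),
        target_positive=int(r.target_positive),
        reference_positive=int(r.reference_positive),
        sample_id=str(r.sample_id),
        true_cnv=None if pd.isna(getattr(r, "true_cnv", None)) else float(r.true_cnv),
    ) for r in df.itertuples()]


def write_expression_tsv(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t", index_label="gene", na_rep=NA)


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])


def write_clinical_tsv(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_clinical_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA])


def write_depth_tsv(tracks: DepthTrackSet, path) -> None:
    pd.concat([tracks.intervals.reset_index(drop=True),
               tracks.counts.reset_index(drop=True)], axis=1
              ).to_csv(path, sep="\t", index=False)


def read_depth_tsv(path, groups: dict[str, str]) -> DepthTrackSet:
    df = pd.read_csv(path, sep="\t")
    intervals = df[["chrom", "start", "end"]]
    counts = df.drop(columns=["chrom", "start", "end"])
    return DepthTrackSet(intervals, counts, groups)


def write_groups_tsv(groups: dict[str, str], path) -> None:
    pd.DataFrame(sorted(groups.items()), columns=["sample", "group"]
                 ).to_csv(path, sep="\t", index=False)


def read_groups_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"].astype(str), df["group"].astype(str)))


def read_gene_list(path) -> list[str]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_gmt(path, set_name: str | None = None) -> list[str]:
    """GMT: one set per line, tab-separated: name, description, genes...
    Returns the named set, or the first set when name is None."""
    for line in Path(path).read_text().splitlines():
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            continue
        if set_name is None or fields[0] == set_name:
            return [g for g in fields[2:] if g]
    raise KeyError(f"gene set {set_name!r} not found in {path}")


def read_gene_set(path, set_name: str | None = None) -> list[str]:
    """Plain list or GMT, decided by extension."""
    if str(path).endswith(".gmt"):
        return read_gmt(path, set_name)
    return read_gene_list(path)


def write_cohort(bundle: CohortBundle, outdir) -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "expression": str(outdir / "expression.tsv"),
        "clinical": str(outdir / "clinical.tsv"),
        "clock": str(outdir / "clock_genes.txt"),
        "wnt": str(outdir / "wnt_genes.txt"),
    }
    write_expression_tsv(bundle.expression, files["expression"])
    write_clinical_tsv(bundle.clinical, files["clinical"])
    Path(files["clock"]).write_text("\n".join(bundle.gene_sets["clock"]) + "\n")
    Path(files["wnt"]).write_text("\n".join(bundle.gene_sets["wnt"]) + "\n")
    return files


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep=NA)


def load_config(path) -> dict:
    """YAML (or JSON, a YAML subset) config file -> dict."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return data


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
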