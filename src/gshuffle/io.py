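"""Tabular and VCF input/output.

All table artifacts are TSV.  Files written by the pipeline begin with
comment lines declaring the seed and config hash so any output can be
traced to (and regenerated from) its run; readers skip '#' lines.
"""

from __future__ import annotations

import hashlib
import json
from typing import Mapping, Optional

import pandas as pd

__all__ = [
    "config_hash",
    "write_table",
    "read_table",
    "read_counts_tsv",
    "write_vcf",
]

_VCF_FILTER_BY_STATUS = {
    "called": "PASS",
    "discarded_fp": "FP_CONTROL",
    "not_called": "LOW_EVIDENCE",
}


def config_hash(config_dict: Mapping) -> str:
    """Stable short hash of a (nested, JSON-serializable) config mapping."""
    canon = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_table(df: pd.DataFrame, path, metadata: Optional[Mapping] = None,
                index: bool = False, index_label=None) -> None:
    """Write a TSV, prefixed with '# key=value' metadata comment lines."""
    with open(path, "w") as fh:
        if metadata:
            for key, value in metadata.items():
                fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_counts_tsv(path) -> pd.DataFrame:
    """Read an amplicon counts TSV and check its schema."""
    df = read_table(path)
    required = {"sample", "locus_id", "total_reads", "alt_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    for col in ("qual_central", "qual_flank_min"):
        if col not in df.columns:
            df[col] = float("nan")
    return df


def write_vcf(path, calls: pd.DataFrame, source: str = "gshuffle",
              metadata: Optional[Mapping] = None) -> None:
    """Write variant calls as a minimal VCF 4.2 file.

    ``calls`` needs columns chrom, pos, id, ref, alt, af, status.  The
    FILTER column encodes the dual-sample filter outcome; AF carries the
    evolved-sample variant read fraction.
    """
    required = {"chrom", "pos", "id", "ref", "alt", "af", "status"}
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"VCF calls table missing columns: {sorted(missing)}")
    lines = ["##fileformat=VCFv4.2", f"##source={source}"]
    if metadata:
        for key, value in metadata.items():
            lines.append(f"##{key}={value}")
    for contig in sorted(pd.unique(calls["chrom"])):
        lines.append(f"##contig=<ID={contig}>")
    lines.append('##INFO=<ID=AF,Number=1,Type=Float,Description="Variant read fraction in the evolved sample">')
    lines.append('##FILTER=<ID=FP_CONTROL,Description="Variant also present at or above the control threshold in the matched wild-type sample">')
    lines.append('##FILTER=<ID=LOW_EVIDENCE,Description="Evolved-sample fraction or base quality below calling thresholds">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    ordered = calls.sort_values(["chrom", "pos"], kind="mergesort")
    for row in ordered.itertuples(index=False):
        filt = _VCF_FILTER_BY_STATUS[row.status]
        ref = row.ref if isinstance(row.ref, str) and row.ref else "N"
        alt = row.alt if isinstance(row.alt, str) and row.alt else "."
        lines.append(
            f"{row.chrom}\t{int(row.pos)}\t{row.id}\t{ref}\t{alt}\t.\t{filt}\tAF={row.af:.6g}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
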