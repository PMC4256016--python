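"""Plain-text I/O: '#'-headed TSV tables and YAML parameter configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def write_tsv(path, df: pd.DataFrame, comments: list[str] | None = None) -> None:
    """Write a table as TSV with a '#'-prefixed header line."""
    path = Path(path)
    with open(path, "w") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        fh.write("# " + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False,
                  float_format="%.10g")


def read_tsv(path) -> pd.DataFrame:
    """Read a '#'-headed TSV written by :func:`write_tsv` (bit-stable
    round trip for the float format used)."""
    path = Path(path)
    header = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header = line[1:].strip().split("\t")
            else:
                break
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if header is not None and len(header) == df.shape[1]:
        df.columns = header
    return df


def write_trace(path, trace) -> None:
    """Three-column pull trace: time_s, extension_nm, force_pN."""
    df = pd.DataFrame({"time_s": trace.time, "extension_nm": trace.extension,
                       "force_pN": trace.force})
    write_tsv(path, df, comments=[f"pull speed {trace.speed} um/s"])


def read_trace(path):
    from .afm_fit import PullTrace
    df = read_tsv(path)
    speed = 1.0
    with open(path) as fh:
        first = fh.readline()
        if "pull speed" in first:
            speed = float(first.split("pull speed")[1].split()[0])
    return PullTrace(time=df["time_s"].to_numpy(),
                     extension=df["extension_nm"].to_numpy(),
                     force=df["force_pN"].to_numpy(), speed=speed)


def write_curve(path, extension_nm, force_pN, comments=None) -> None:
    """Two-column force-extension curve TSV."""
    df = pd.DataFrame({"extension_nm": np.asarray(extension_nm),
                       "force_pN": np.asarray(force_pN)})
    write_tsv(path, df, comments=comments)


def write_manifest(path, manifest: dict) -> None:
    """Machine-readable run manifest (condition, seeds, replicate count,
    software version)."""
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
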