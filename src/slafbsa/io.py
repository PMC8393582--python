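"""Readers and writers for the toolkit's plain-text table formats.

All tables are UTF-8 with ``#``-prefixed ``key=value`` metadata header
lines (version, seed, config hash), tab-separated for locus-level tables
and comma-separated for sample-level tables, with ``NA`` marking missing
values.  Coordinates are 1-based inclusive.  Write-then-read round-trips
reproduce the in-memory frames exactly up to dtype.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__


def config_hash(obj) -> str:
    """Short stable hash of a (nested) configuration mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def standard_metadata(seed: int, cfg_hash: str = "", **extra) -> dict:
    meta = {"slafbsa_version": __version__, "seed": seed, "coordinates": "1-based"}
    if cfg_hash:
        meta["config_hash"] = cfg_hash
    meta.update(extra)
    return meta


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    metadata: dict | None = None,
    sep: str = "\t",
) -> None:
    """Write a table with ``# key=value`` header lines, ``NA`` for missing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep=sep, index=False, na_rep="NA", lineterminator="\n")


def read_table(path: str | Path, sep: str = "\t") -> tuple[pd.DataFrame, dict]:
    """Read a table written by :func:`write_table`; returns (frame, metadata)."""
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep=sep, na_values=["NA"], keep_default_na=False)
    return df, meta


# convenience wrappers, fixing the separator conventions per format

def write_depth_table(df, path, metadata=None):
    write_table(df, path, metadata, sep="\t")


def read_depth_table(path):
    return read_table(path, sep="\t")


def write_genotype_matrix(df: pd.DataFrame, path, metadata=None):
    """Genotype strings, individuals x loci; index column ``id``."""
    out = df.reset_index() if df.index.name else df
    write_table(out, path, metadata, sep="\t")


def read_genotype_matrix(path) -> tuple[pd.DataFrame, dict]:
    df, meta = read_table(path, sep="\t")
    first = df.columns[0]
    return df.set_index(first), meta


def write_phenotypes(df, path, metadata=None):
    write_table(df, path, metadata, sep=",")


def read_phenotypes(path):
    return read_table(path, sep=",")


def write_json_report(obj, path, metadata=None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"metadata": metadata or {}, "report": obj}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def vcf_to_depth_table(path: str | Path) -> pd.DataFrame:
    """Import shim: map a 2-sample VCF with AD fields to the depth table.

    The two samples are taken as the HEBV and LEBV pools in column order.
    Only biallelic SNP records with an AD FORMAT field are converted;
    quality comes from the QUAL column.
    """
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        samples: list[str] = []
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.rstrip("\n").split("\t")[9:]
                if len(samples) != 2:
                    raise ValueError("expected exactly two pool samples in VCF")
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, pos, vid, ref, alt, qual, _flt, _info, fmt = parts[:9]
            if len(ref) != 1 or len(alt) != 1 or alt == ".":
                continue
            keys = fmt.split(":")
            if "AD" not in keys:
                continue
            ad_idx = keys.index("AD")
            depths = {}
            for tag, sample in zip(("H", "L"), parts[9:11]):
                ad = sample.split(":")[ad_idx].split(",")
                counts = dict.fromkeys("ACGT", 0)
                counts[ref] = int(ad[0])
                counts[alt] = int(ad[1])
                for b in "ACGT":
                    depths[f"{b}_{tag}"] = counts[b]
            rows.append(
                {
                    "locus_id": vid if vid != "." else f"{chrom}:{pos}",
                    "chrom": chrom,
                    "pos": int(pos),
                    "ref": ref,
                    "alt": alt,
                    **depths,
                    "Q": float(qual) if qual != "." else float("nan"),
                }
            )
    return pd.DataFrame(rows)
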