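"""Readers and writers for the plain-text formats the pipeline consumes.

All genomic coordinates are 0-based, half-open throughout the package.
CpG positions refer to the C of the CpG dinucleotide on the forward strand;
reverse-strand calls (at pos+1) are merged into the forward-strand record.

Methylation call tables come in two dialects, sniffed from column count:

* ``coverage`` (6 columns): chrom, start, end, percent_methylated,
  count_methylated, count_unmethylated.  The percent column is recomputed
  from the counts and must agree within 0.5 to guard against corrupt files.
* ``counts`` (5 columns, bedGraph-with-counts): chrom, start, end,
  count_methylated, count_unmethylated.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


class CpGRecord(NamedTuple):
    """One CpG methylation call: forward-strand position plus read counts."""

    chrom: str
    pos: int
    n_meth: int
    n_total: int
    sample: tuple[str, str] | None = None  # (individual, tissue)


class ParseError(ValueError):
    pass


def _merge_strands(df: pd.DataFrame) -> pd.DataFrame:
    """Merge reverse-strand calls (pos+1) into their forward-strand record.

    Within a run of consecutive positions, every second position is taken to
    be the G-strand call of the preceding C and its counts are added there.
    """
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    pos = df["pos"].to_numpy()
    same_chrom = df["chrom"].to_numpy()
    follows = np.zeros(len(df), dtype=bool)
    if len(df) > 1:
        follows[1:] = (np.diff(pos) == 1) & (same_chrom[1:] == same_chrom[:-1])
    if not follows.any():
        return df
    # alternate within runs of consecutive positions: a position is a reverse
    # call iff its predecessor is a forward call (CpGs on one strand are >= 2
    # bp apart, so p and p+1 cannot both be forward-strand CpGs)
    is_rev = np.zeros(len(df), dtype=bool)
    i = 1
    n = len(df)
    while i < n:
        if follows[i] and not is_rev[i - 1]:
            is_rev[i] = True
        i += 1
    if not is_rev.any():
        return df
    target = np.arange(n) - 1
    nm = df["n_meth"].to_numpy().copy()
    nt = df["n_total"].to_numpy().copy()
    np.add.at(nm, target[is_rev], nm[is_rev])
    np.add.at(nt, target[is_rev], nt[is_rev])
    out = df.loc[~is_rev].copy()
    out["n_meth"] = nm[~is_rev]
    out["n_total"] = nt[~is_rev]
    return out.reset_index(drop=True)


def read_cpg_table(
    path,
    sample: tuple[str, str] | None = None,
    dialect: str | None = None,
    merge_strands: bool = True,
    percent_tol: float = 0.5,
) -> pd.DataFrame:
    """Read a per-CpG methylation call table.

    Returns a DataFrame with columns ``chrom, pos, n_meth, n_total``; the
    ``sample`` label, if given, is stored in ``df.attrs["sample"]``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if dialect is None:
                dialect = {6: "coverage", 5: "counts"}.get(len(fields))
                if dialect is None:
                    raise ParseError(
                        f"{path}:{lineno}: cannot sniff dialect from "
                        f"{len(fields)} columns"
                    )
            try:
                if dialect == "coverage":
                    chrom, start, _end, pct, nm, nu = fields[:6]
                    pct = float(pct)
                else:
                    chrom, start, _end, nm, nu = fields[:5]
                    pct = None
                pos, nm, nu = int(start), int(nm), int(nu)
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed line: {line!r}") from exc
            nt = nm + nu
            if nm < 0 or nu < 0:
                raise ParseError(f"{path}:{lineno}: negative read count")
            if pct is not None and nt > 0 and abs(pct - 100.0 * nm / nt) > percent_tol:
                raise ParseError(
                    f"{path}:{lineno}: percent column {pct} disagrees with "
                    f"counts {nm}/{nt}"
                )
            rows.append((chrom, pos, nm, nt))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "n_meth", "n_total"])
    if merge_strands:
        df = _merge_strands(df)
    df.attrs["sample"] = sample
    return df


def write_cpg_table(df: pd.DataFrame, path, dialect: str = "coverage") -> None:
    """Write a CpG call table in ``coverage`` or ``counts`` dialect."""
    out = df.copy()
    out["end"] = out["pos"] + 1
    out["n_unmeth"] = out["n_total"] - out["n_meth"]
    with open(path, "w") as fh:
        if dialect == "coverage":
            with np.errstate(invalid="ignore"):
                pct = np.where(
                    out["n_total"] > 0, 100.0 * out["n_meth"] / out["n_total"], 0.0
                )
            for (c, p, e, nm, nu), f in zip(
                out[["chrom", "pos", "end", "n_meth", "n_unmeth"]].itertuples(
                    index=False
                ),
                pct,
            ):
                fh.write(f"{c}\t{p}\t{e}\t{f:.6g}\t{nm}\t{nu}\n")
        elif dialect == "counts":
            for c, p, e, nm, nu in out[
                ["chrom", "pos", "end", "n_meth", "n_unmeth"]
            ].itertuples(index=False):
                fh.write(f"{c}\t{p}\t{e}\t{nm}\t{nu}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def iter_cpg_records(df: pd.DataFrame) -> Iterable[CpGRecord]:
    sample = df.attrs.get("sample")
    for chrom, pos, nm, nt in df[["chrom", "pos", "n_meth", "n_total"]].itertuples(
        index=False
    ):
        yield CpGRecord(chrom, int(pos), int(nm), int(nt), sample)


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path) -> pd.DataFrame:
    """Read a genotype table (TSV or minimal VCF) into additive coding.

    Returns a DataFrame with columns ``snv_id, chrom, pos`` followed by one
    column per individual holding additive genotypes in {0, 1, 2} (NaN for
    missing).  VCF positions (1-based) are converted to 0-based; non-biallelic
    VCF records are skipped with a logged warning.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF") or path.suffix == ".vcf":
        return _read_vcf_genotypes(path)
    return _read_tsv_genotypes(path)


def _read_vcf_genotypes(path) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        individuals = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                log.warning("skipping non-biallelic record %s:%s", rec.chrom, rec.pos)
                continue
            row = [rec.id or f"{rec.chrom}_{rec.start}", rec.chrom, rec.start]
            for ind in individuals:
                gt = rec.samples[ind].get("GT")
                if gt is None or any(a is None for a in gt):
                    row.append(np.nan)
                else:
                    row.append(float(sum(gt)))
            rows.append(row)
    df = pd.DataFrame(rows, columns=["snv_id", "chrom", "pos"] + individuals)
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def _read_tsv_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"snv_id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise ParseError(f"genotype TSV must have columns {sorted(required)}")
    ind_cols = [c for c in df.columns if c not in required]
    for c in ind_cols:
        vals = df[c].dropna().unique()
        bad = set(vals) - {0, 1, 2, 0.0, 1.0, 2.0}
        if bad:
            raise ParseError(f"genotype column {c!r} has values outside {{0,1,2}}: {bad}")
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_genotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def genotype_matrix(gt: pd.DataFrame, individuals: list[str]) -> np.ndarray:
    """Additive genotype matrix (n_snv, n_individuals), NaN for missing."""
    missing = [i for i in individuals if i not in gt.columns]
    if missing:
        raise KeyError(f"individuals absent from genotype table: {missing}")
    return gt[individuals].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# intervals & misc


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (0-based, half-open); strand, if present, is ignored."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed BED line") from exc
            name = fields[3] if len(fields) > 3 else ""
            score = fields[4] if len(fields) > 4 else ""
            rows.append((chrom, start, end, name, score))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
    if (df["name"] == "").all():
        df = df[["chrom", "start", "end"]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def load_config(path) -> dict:
    """Load a YAML config (bin_size, min_depth, tissue set, thresholds...)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError("config must be a mapping")
    return cfg
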