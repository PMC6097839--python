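"""Readers and writers for the pipeline's plain-text formats.

All tables are TSV (gzip accepted transparently via the ``.gz`` suffix):
counts (feature id first column, ``spike:`` prefix for spike rows, samples
named ``<age>_<assay>_rep<k>``), spike reference, expression matrices with a
``# mode=`` header, TE tables, ground truth, per-gene positional profiles,
BED12 annotation (main ORF as the thick region, uORFs as upstream blocks,
0-based half-open) and GMT gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataFormatError
from .models import (
    CountMatrix,
    ExpressionMatrix,
    GeneModel,
    PositionalProfile,
    SPIKE_PREFIX,
    SpikeInReference,
    TETable,
    parse_sample_name,
)

FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------- counts TSV

def write_counts(cm: CountMatrix, path: str | Path) -> None:
    df = cm.counts.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_counts(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "feature_id":
        raise DataFormatError(f"{path}: first column must be 'feature_id'")
    dupes = df.index[df.index.duplicated()]
    if len(dupes):
        first = df.index.get_loc(dupes[0])
        line = (first.start if isinstance(first, slice) else int(np.atleast_1d(first)[0])) + 2
        raise DataFormatError(f"{path}: duplicate feature id {dupes[0]!r} (line {line})")
    for col in df.columns:
        parse_sample_name(col)
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.number):
            bad = vals[pd.to_numeric(vals, errors="coerce").isna()].index[0]
            line = df.index.get_loc(bad) + 2
            raise DataFormatError(f"{path}: non-numeric count at line {line}")
        if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
            bad = vals.index[(vals < 0) | (vals != np.round(vals))][0]
            line = df.index.get_loc(bad) + 2
            raise DataFormatError(
                f"{path}: counts must be non-negative integers (line {line})"
            )
    return CountMatrix(counts=df.astype(np.int64))


# ----------------------------------------------------------- spike reference

def write_spike_reference(spikes: list[SpikeInReference], path: str | Path) -> None:
    # no float_format: shortest-roundtrip repr keeps nominal amounts exact
    pd.DataFrame(
        {
            "spike_id": [s.spike_id for s in spikes],
            "length_nt": [s.length_nt for s in spikes],
            "molecules_per_cell_equivalent": [
                s.molecules_per_cell_equivalent for s in spikes
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def read_spike_reference(path: str | Path) -> list[SpikeInReference]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"spike_id", "length_nt", "molecules_per_cell_equivalent"}
    if set(df.columns) != required:
        raise DataFormatError(f"{path}: expected columns {sorted(required)}")
    return [
        SpikeInReference(
            spike_id=str(r.spike_id),
            length_nt=int(r.length_nt),
            molecules_per_cell_equivalent=float(r.molecules_per_cell_equivalent),
        )
        for r in df.itertuples()
    ]


# --------------------------------------------------------- expression matrix

def write_expression(em: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    header = f"# mode={em.mode}\n# steps={'|'.join(em.steps)}\n"
    body = em.values.copy()
    body.index.name = "gene_id"
    import gzip

    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write(header)
        body.to_csv(fh, sep="\t", float_format=FLOAT_FMT)


def read_expression(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    import gzip

    opener = gzip.open if path.suffix == ".gz" else open
    mode = steps = None
    with opener(path, "rt") as fh:
        pos = fh.tell()
        for line in iter(fh.readline, ""):
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "mode":
                mode = val.strip()
            elif key.strip() == "steps":
                steps = tuple(s for s in val.strip().split("|") if s)
            pos = fh.tell()
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if mode is None:
        raise DataFormatError(f"{path}: missing '# mode=' header")
    return ExpressionMatrix(values=df, mode=mode, steps=steps or ())


# ------------------------------------------------------------------ TE table

TE_COLUMNS = [
    "te_young", "te_mid", "te_old", "log2fc_mid", "log2fc_old",
    "p", "q", "rank", "status", "significant_decrease",
]


def write_te_table(tetable: TETable, path: str | Path) -> None:
    cols = [c for c in TE_COLUMNS if c in tetable.table.columns]
    out = tetable.table[cols].copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_te_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "status" not in df.columns:
        raise DataFormatError(f"{path}: not a TE table (no 'status' column)")
    return df


# ------------------------------------------------------------- ground truth

def write_truth(genes: pd.DataFrame, path: str | Path) -> None:
    out = genes.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ------------------------------------------------------------------- BED12

@dataclass(frozen=True)
class AnnotationRecord:
    """Gene geometry recovered from a BED12 record."""

    gene_id: str
    orf_length_nt: int
    leader_nt: int
    uorfs: tuple[tuple[int, int], ...]

    @property
    def length_kb(self) -> float:
        return self.orf_length_nt / 1000.0

    @property
    def n_codons(self) -> int:
        return self.orf_length_nt // 3


def write_annotation(models: list[GeneModel], path: str | Path) -> None:
    """One BED12 record per gene on its own contig (0-based, half-open).

    The main ORF is the thick region; uORFs are blocks that end before
    thickStart.  chromStart is the first block start, as browsers require.
    """
    lines = []
    for m in models:
        thick_start = m.leader_nt
        thick_end = m.leader_nt + m.orf_length_nt
        blocks = [(off, length) for off, length in sorted(m.uorfs)]
        blocks.append((thick_start, m.orf_length_nt))
        chrom_start = blocks[0][0]
        chrom_end = thick_end
        sizes = ",".join(str(length) for _off, length in blocks)
        starts = ",".join(str(off - chrom_start) for off, _length in blocks)
        lines.append(
            "\t".join(
                [
                    m.gene_id, str(chrom_start), str(chrom_end), m.gene_id, "0", "+",
                    str(thick_start), str(thick_end), "0",
                    str(len(blocks)), sizes, starts,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation(path: str | Path) -> dict[str, AnnotationRecord]:
    """Parse BED12: gene length from the thick region, uORFs from upstream blocks."""
    records: dict[str, AnnotationRecord] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith(("#", "track", "browser")):
            continue
        fields = raw.split("\t")
        if len(fields) < 12:
            raise DataFormatError(f"{path}:{ln}: expected 12 BED fields")
        name = fields[3]
        chrom_start, chrom_end = int(fields[1]), int(fields[2])
        thick_start, thick_end = int(fields[6]), int(fields[7])
        if thick_start >= thick_end:
            raise DataFormatError(f"{path}:{ln}: thickStart >= thickEnd")
        n_blocks = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise DataFormatError(f"{path}:{ln}: blockCount mismatch")
        uorfs = []
        for size, start in zip(sizes, starts):
            abs_start = chrom_start + start
            abs_end = abs_start + size
            if abs_start < chrom_start or abs_end > chrom_end:
                raise DataFormatError(f"{path}:{ln}: block outside record bounds")
            if abs_end <= thick_start:
                uorfs.append((abs_start, size))
        if name in records:
            raise DataFormatError(f"{path}:{ln}: duplicate gene {name!r}")
        records[name] = AnnotationRecord(
            gene_id=name,
            orf_length_nt=thick_end - thick_start,
            leader_nt=thick_start,
            uorfs=tuple(sorted(uorfs)),
        )
    return records


def gene_lengths_kb(annotation: dict[str, AnnotationRecord]) -> pd.Series:
    return pd.Series({g: rec.length_kb for g, rec in annotation.items()}, name="length_kb")


# ----------------------------------------------------------------- profiles

def write_profiles(profiles: list[PositionalProfile], path: str | Path) -> None:
    rows = []
    for prof in profiles:
        for i, c in enumerate(prof.main_counts):
            rows.append((prof.gene_id, prof.age or "", "main", i, c))
        for k, u in enumerate(prof.uorf_counts):
            for i, c in enumerate(u):
                rows.append((prof.gene_id, prof.age or "", f"uorf{k + 1}", i, c))
    pd.DataFrame(
        rows, columns=["gene_id", "age", "region", "codon", "count"]
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_profiles(path: str | Path) -> list[PositionalProfile]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "age", "region", "codon", "count"}
    if not required <= set(df.columns):
        raise DataFormatError(f"{path}: expected columns {sorted(required)}")
    out = []
    for (gid, age), sub in df.groupby(["gene_id", "age"], dropna=False, sort=True):
        main = sub[sub["region"] == "main"].sort_values("codon")["count"].to_numpy(float)
        uorfs = []
        for region in sorted(r for r in sub["region"].unique() if r.startswith("uorf")):
            uorfs.append(
                sub[sub["region"] == region].sort_values("codon")["count"].to_numpy(float)
            )
        out.append(
            PositionalProfile(
                gene_id=str(gid),
                main_counts=main,
                uorf_counts=tuple(uorfs),
                age=None if pd.isna(age) or age == "" else str(age),
            )
        )
    return out


# ---------------------------------------------------------------------- GMT

def write_gmt(collections: dict[str, set], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for name in collections:
        desc = (descriptions or {}).get(name, "")
        members = "\t".join(sorted(collections[name]))
        lines.append(f"{name}\t{desc}\t{members}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> dict[str, set]:
    collections: dict[str, set] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < 3:
            raise DataFormatError(f"{path}:{ln}: GMT needs name, description, members")
        if fields[0] in collections:
            raise DataFormatError(f"{path}:{ln}: duplicate set {fields[0]!r}")
        collections[fields[0]] = {m for m in fields[2:] if m}
    return collections


# ------------------------------------------------------------- gene lists

def read_gene_list(path: str | Path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


def read_pair_table(path: str | Path) -> pd.Series:
    """Two-column TSV keyed by gene_id -> value (for dataset comparisons)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise DataFormatError(f"{path}: expected exactly two columns")
    df.columns = ["gene_id", "value"]
    if df["gene_id"].duplicated().any():
        dupe = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise DataFormatError(f"{path}: duplicate gene {dupe!r}")
    return df.set_index("gene_id")["value"]
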