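"""Readers and writers for the pipeline's file formats.

Canonical tabular dialect: TSV, UTF-8, header row, no quoting; leading
``#`` lines are ignored.  BED coordinates are 0-based half-open.  GMT files
follow the MSigDB convention (set id, free-text description, member genes).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from micropat.maturation import GeneSetCollection
from micropat.synthetic import BgcRecord, CoverageObservation, PlantedTruth

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_bgc_reference",
    "write_bgc_reference",
    "read_coverage_table",
    "write_coverage_table",
    "read_bed_coverage",
    "read_gmt",
    "write_gmt",
    "read_truth",
    "write_truth",
    "write_graphml",
    "file_checksum",
]

logger = logging.getLogger(__name__)

_META_COLUMNS = ["sample_id", "mouse_id", "sex", "treatment", "day"]


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_count_table(
    path: str | Path,
    orientation: str = "samples_by_features",
) -> pd.DataFrame:
    """Read an integer count table with first-column identifiers.

    ``orientation`` declares how the file on disk is laid out; the returned
    frame always has rows = samples and columns = features (the file is
    transposed on read when ``orientation="features_by_samples"``).
    Duplicate identifiers and non-integer or negative cells are rejected
    with the offending address.
    """
    if orientation not in ("samples_by_features", "features_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_tsv(path, index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row identifiers {dupes[:5]}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate column identifiers {dupes[:5]}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals % 1 != 0) | (vals < 0)
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"{path}: cell (row {row!r}, column {col!r}) is not a "
                "non-negative integer"
            )
    df = df.astype("int64")
    if orientation == "features_by_samples":
        df = df.T
    return df


def write_count_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a count table exactly as laid out in memory."""
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = _read_tsv(path)
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing columns {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id values")
    meta["day"] = meta["day"].astype(int)
    return meta[_META_COLUMNS]


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta[_META_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bgc_reference(path: str | Path) -> list[BgcRecord]:
    df = _read_tsv(path)
    records = []
    for _, row in df.iterrows():
        fams = str(row["orf_families"])
        records.append(
            BgcRecord(
                bgc_id=str(row["bgc_id"]),
                length_bp=int(row["length_bp"]),
                orf_families=frozenset(f for f in fams.split(";") if f),
                taxon=str(row.get("taxon", "unknown")),
                characterized=bool(row.get("characterized", False)),
                product_class=str(row.get("product_class", "unknown")),
            )
        )
    ids = [r.bgc_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate bgc_id values")
    return records


def write_bgc_reference(bgcs: list[BgcRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "bgc_id": [b.bgc_id for b in bgcs],
            "length_bp": [b.length_bp for b in bgcs],
            "orf_families": [";".join(sorted(b.orf_families)) for b in bgcs],
            "taxon": [b.taxon for b in bgcs],
            "characterized": [b.characterized for b in bgcs],
            "product_class": [b.product_class for b in bgcs],
        }
    ).to_csv(path, sep="\t", index=False)


def read_coverage_table(path: str | Path) -> list[CoverageObservation]:
    df = _read_tsv(path)
    return [
        CoverageObservation(
            sample_id=str(r["sample_id"]),
            bgc_id=str(r["bgc_id"]),
            n_reads=int(r["n_reads"]),
            read_len=int(r["read_len"]),
            covered_bases=int(r["covered_bases"]),
        )
        for _, r in df.iterrows()
    ]


def write_coverage_table(obs: list[CoverageObservation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [o.sample_id for o in obs],
            "bgc_id": [o.bgc_id for o in obs],
            "n_reads": [o.n_reads for o in obs],
            "read_len": [o.read_len for o in obs],
            "covered_bases": [o.covered_bases for o in obs],
        }
    ).to_csv(path, sep="\t", index=False)


def read_bed_coverage(
    path: str | Path, bgcs: list[BgcRecord], read_len: int = 100
) -> list[CoverageObservation]:
    """Summarize per-read BED intervals into coverage observations.

    Expects BED3+ lines ``bgc_id <TAB> start <TAB> end <TAB> sample_id``
    (0-based half-open).  Per (sample, bgc): N = line count, C = length of
    the interval union clipped to [0, L_BGC).  Intervals extending past the
    BGC end are clipped with a warning; ``end <= start`` is an error.
    """
    by_id = {b.bgc_id: b for b in bgcs}
    groups: dict[tuple[str, str], list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: need bgc_id, start, end, sample_id")
            bgc_id, start, end, sample_id = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if end <= start:
                raise ValueError(f"{path}:{ln}: end <= start")
            if bgc_id not in by_id:
                raise ValueError(f"{path}:{ln}: unknown BGC {bgc_id!r}")
            L = by_id[bgc_id].length_bp
            if end > L:
                logger.warning("%s:%d: interval beyond BGC end, clipped to %d", path, ln, L)
                end = L
            if start >= L:
                continue
            groups.setdefault((sample_id, bgc_id), []).append((start, end))
    observations = []
    for (sample_id, bgc_id), intervals in sorted(groups.items()):
        intervals.sort()
        covered = 0
        cur_s, cur_e = intervals[0]
        for s, e in intervals[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
        covered += cur_e - cur_s
        observations.append(
            CoverageObservation(sample_id, bgc_id, len(intervals), read_len, covered)
        )
    return observations


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    sets = {}
    members_all: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs id, description, >=1 gene")
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
            members_all |= sets[parts[0]]
    return GeneSetCollection(
        sets=sets, universe=frozenset(universe) if universe else frozenset(members_all)
    )


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets.sets):
            genes = "\t".join(sorted(sets.sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def read_truth(path: str | Path) -> PlantedTruth:
    return PlantedTruth.from_json(Path(path).read_text())


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """Deterministic GraphML export (nodes/edges already insertion-ordered)."""
    nx.write_graphml(graph, str(path))


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(doc: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))
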