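"""Shared data model and plain-text I/O.

All tables travel as pandas DataFrames wrapped in light validating
containers; networks are :class:`networkx.Graph` objects with a fixed
attribute schema (see :data:`EDGE_ATTRS`).  Every writer emits a canonical
TSV dialect — tab-separated, UTF-8, ``.`` decimal, no quoting, fixed column
order — so outputs are diffable and round trips are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("cooccurnet")

#: Sampling months in temporal order (no November cruise).
MONTHS: tuple[str, ...] = ("Jul", "Aug", "Sept", "Oct", "Dec")
#: Water-depth layers, surface to bottom.
DEPTHS: tuple[str, ...] = ("surface", "middle", "bottom")
#: Plankton size fractions: free-living (0.22–3 µm), nanoparticle-associated
#: (3–20 µm) and microparticle-associated (>20 µm).
FRACTIONS: tuple[str, ...] = ("FL", "NP", "MP")
#: Environmental parameters measured per water sample.
ENV_VARS: tuple[str, ...] = (
    "temperature", "salinity", "NOx", "phosphate", "silicate", "DO", "pH", "Chl_a",
)
#: Taxonomic ranks, domain to genus.
RANKS: tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus")

#: Node-attribute schema for co-occurrence networks.
NODE_ATTRS = ("kind", "fraction", "phylum", "family", "order")
#: Edge-attribute schema for co-occurrence networks.
EDGE_ATTRS = ("rho", "q", "sign")


class FormatError(ValueError):
    """A file violated the canonical table format."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

class OtuTable:
    """Integer OTU × sample count matrix.

    Parameters
    ----------
    counts
        DataFrame with OTU ids as the index and sample ids as columns.
        Cells must be finite, non-negative integers.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise FormatError(f"duplicate OTU id {dup!r}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            bad = ~np.isfinite(values.astype(float))
            if bad.any():
                i, j = map(int, np.argwhere(bad)[0])
                raise FormatError(
                    f"non-finite count at OTU {counts.index[i]!r}, "
                    f"sample {counts.columns[j]!r}"
                )
            frac = values.astype(float) % 1 != 0
            if frac.any():
                i, j = map(int, np.argwhere(frac)[0])
                raise FormatError(
                    f"non-integer count at OTU {counts.index[i]!r}, "
                    f"sample {counts.columns[j]!r}"
                )
            counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise FormatError("negative counts are not allowed")
        self.counts = counts

    @property
    def otu_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.shape
        return f"OtuTable({n} OTUs x {m} samples)"


@dataclass
class AnalysisBundle:
    """All tables of one study, aligned on a common sample set."""

    otu: OtuTable
    meta: pd.DataFrame
    env: pd.DataFrame | None = None
    phyto: pd.DataFrame | None = None
    taxonomy: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> pd.Index:
        return self.otu.sample_ids

    def months(self) -> list[str]:
        present = set(self.meta["month"])
        return [m for m in MONTHS if m in present]


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the closed vocabularies of the sampling design."""
    required = {"month", "station", "depth", "fraction"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    bad_month = set(meta["month"]) - set(MONTHS)
    if bad_month:
        raise FormatError(f"unknown month labels: {sorted(bad_month)}")
    bad_depth = set(meta["depth"]) - set(DEPTHS)
    if bad_depth:
        raise FormatError(f"unknown depth labels: {sorted(bad_depth)}")
    bad_frac = set(meta["fraction"]) - set(FRACTIONS)
    if bad_frac:
        raise FormatError(f"unknown fraction labels: {sorted(bad_frac)}")
    return meta


def join_tables(
    otu: OtuTable,
    meta: pd.DataFrame,
    env: pd.DataFrame | None = None,
    phyto: pd.DataFrame | None = None,
    taxonomy: pd.DataFrame | None = None,
    strict: bool = False,
) -> AnalysisBundle:
    """Align all tables on the intersection of their sample ids.

    Samples missing from any table are dropped with a logged warning, or
    raise ``FormatError`` in strict mode.  An empty intersection is always
    an error.
    """
    validate_metadata(meta)
    common = otu.sample_ids.intersection(meta.index)
    if env is not None:
        common = common.intersection(env.index)
    if phyto is not None:
        common = common.intersection(phyto.columns)
    if len(common) == 0:
        raise FormatError("no common sample ids between tables")
    universe = set(otu.sample_ids) | set(meta.index)
    if env is not None:
        universe |= set(env.index)
    if phyto is not None:
        universe |= set(phyto.columns)
    total = len(universe) - len(common)
    if total:
        if strict:
            raise FormatError(f"{total} samples not shared by all tables")
        logger.warning("dropping %d samples not shared by all tables", total)
    keep = [s for s in otu.sample_ids if s in set(common)]
    return AnalysisBundle(
        otu=OtuTable(otu.counts[keep]),
        meta=meta.loc[keep],
        env=None if env is None else env.loc[keep],
        phyto=None if phyto is None else phyto[keep],
        taxonomy=taxonomy,
    )


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def read_otu_table(path: str | Path) -> OtuTable:
    """Read an OTU count table (first column OTU id, samples in columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=np.int64)
    for col in df.columns:
        for otu, cell in df[col].items():
            try:
                out.at[otu, col] = int(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-integer cell {cell!r} at OTU {otu!r}, sample {col!r}"
                ) from None
    return OtuTable(out)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta[["month", "station", "depth", "fraction"]].copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_env_table(path: str | Path) -> pd.DataFrame:
    env = pd.read_csv(path, sep="\t", index_col=0)
    non_numeric = [c for c in env.columns if not np.issubdtype(env[c].dtype, np.number)]
    if non_numeric:
        raise FormatError(f"non-numeric environmental columns: {non_numeric}")
    return env


def write_env_table(env: pd.DataFrame, path: str | Path) -> None:
    out = env.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", lineterminator="\n", float_format="%.6g")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a Silva-style lineage table: otu_id + one column per rank."""
    tax = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    missing = [r for r in RANKS if r not in tax.columns]
    if missing:
        raise FormatError(f"taxonomy missing ranks: {missing}")
    if tax.index.has_duplicates:
        raise FormatError("duplicate OTU id in taxonomy")
    return tax.fillna("unclassified")


def write_taxonomy(tax: pd.DataFrame, path: str | Path) -> None:
    out = tax[list(RANKS)].copy()
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# network export / import
# ---------------------------------------------------------------------------

def _clean_attrs(d: Mapping) -> dict:
    return {k: v for k, v in d.items() if v is not None}


def write_graphml(network: nx.Graph, path: str | Path) -> None:
    """Write a network as GraphML with all node/edge attributes preserved."""
    g = nx.Graph(**_clean_attrs(network.graph))
    for n, d in network.nodes(data=True):
        g.add_node(n, **_clean_attrs(d))
    for u, v, d in network.edges(data=True):
        g.add_edge(u, v, **_clean_attrs(d))
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_edge_list(network: nx.Graph, path: str | Path) -> None:
    """Write a Cytoscape-importable TSV edge list (source/target/rho/q/sign)."""
    rows = []
    for u, v, d in sorted(network.edges(data=True)):
        rows.append({
            "source": u,
            "target": v,
            "rho": d.get("rho", ""),
            "q": d.get("q", ""),
            "sign": d.get("sign", ""),
        })
    pd.DataFrame(rows, columns=["source", "target", "rho", "q", "sign"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n", float_format="%.6g"
    )


# ---------------------------------------------------------------------------
# flat key-value config files
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    """Parse a flat ``key = value`` config file.

    Blank lines and ``#`` comments are ignored; values are cast to int,
    float or bool where possible, and comma-separated values become lists.
    """
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        out[key.strip()] = _cast(value.strip())
    return out


def _cast(value: str):
    if "," in value:
        return [_cast(v.strip()) for v in value.split(",")]
    for caster in (int, float):
        try:
            return caster(value)
        except ValueError:
            pass
    if value.lower() in ("true", "false"):
        return value.lower() == "true"
    return value
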