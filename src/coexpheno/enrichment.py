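"""Hypergeometric over-representation of module members in gene-set
collections (GMT format), with BH-FDR within each module's family of sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .association import bh_fdr
from .expression import FormatError


@dataclass
class GeneSetCollection:
    """Named gene sets (order-preserving), with a source description."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, then members.

    Duplicate members within a set are stored once; a line with fewer than
    three fields is a format error reported with its line number.
    """
    path = Path(path)
    coll = GeneSetCollection(source=str(path))
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
        name = fields[0]
        if name in coll.sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        seen: dict[str, None] = {}
        for g in fields[2:]:
            if g:
                seen.setdefault(g)
        coll.sets[name] = list(seen)
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description] + members) for name, members in coll.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def enrich_module(
    module_genes: Sequence[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    min_set_size: int = 5,
    max_set_size: int = 2000,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a module in each set.

    Sets are intersected with the universe first; sets with fewer than
    ``min_set_size`` or more than ``max_set_size`` universe members are
    skipped.  P(X >= k) uses population = |universe|, successes =
    |set & universe|, draws = |module|.  BH-FDR is applied across the
    module's tested sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    module = set(module_genes)
    if not module <= universe:
        raise ValueError("module genes must be a subset of the universe")
    rows = []
    for name, members in collection.sets.items():
        in_universe = universe.intersection(members)
        K = len(in_universe)
        if K < min_set_size or K > max_set_size:
            continue
        k = len(module & in_universe)
        # upper tail P(X >= k)
        p = float(hypergeom.sf(k - 1, len(universe), K, len(module)))
        rows.append((name, k, K, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"])
    table["fdrp"] = bh_fdr(table["p"].to_numpy()) if len(table) else []
    return table


def enrich_all_modules(
    partition,
    collection: GeneSetCollection,
    universe: Iterable[str],
    labels: Sequence[int] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Run :func:`enrich_module` per module; FDR stays within-module."""
    universe = list(universe)
    frames = []
    for label in labels if labels is not None else sorted(partition.module_sizes):
        tab = enrich_module(partition.module_genes(label), collection, universe, **kwargs)
        tab.insert(0, "module", label)
        frames.append(tab)
    if not frames:
        return pd.DataFrame(columns=["module", "set", "overlap", "set_size", "p", "fdrp"])
    return pd.concat(frames, ignore_index=True)
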