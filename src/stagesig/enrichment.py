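"""Fisher exact over/under-representation of a gene list against gene sets.

For each gene set the 2x2 table (in-set / out-of-set x in-input / out-of-
input) over a fixed universe is tested with the two-sided Fisher exact test
(sum of table probabilities <= the observed table's, PANTHER-style), the
expected overlap is the hypergeometric mean input * category / universe, and
the direction is "over" when observed > expected, "under" when observed <
expected, "none" on an exact tie.  Raw p-values are BH-adjusted across the
sets actually supplied — FDR values therefore depend on the collection
tested, not on any external database release.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dge import bh_adjust
from .errors import ParseError, ValidationError

__all__ = ["GeneSetCollection", "read_gmt", "fisher_enrichment"]


@dataclass
class GeneSetCollection:
    """Named gene sets harmonized against a reference universe.

    Members outside the universe are dropped at construction and counted in
    ``out_of_universe`` (per-set).  Case-sensitive exact symbol matching.
    """

    sets: dict[str, set[str]]
    universe: frozenset[str]
    names: dict[str, str] = field(default_factory=dict)
    out_of_universe: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_sets(
        cls,
        sets: Mapping[str, Iterable[str]],
        universe: Iterable[str],
        names: Mapping[str, str] | None = None,
    ) -> "GeneSetCollection":
        uni = frozenset(universe)
        if not uni:
            raise ValidationError("empty universe")
        harmonized: dict[str, set[str]] = {}
        dropped: dict[str, int] = {}
        for sid, members in sets.items():
            members = set(members)
            inside = members & uni
            if not inside:
                raise ValidationError(f"gene set {sid!r} has no members in the universe")
            harmonized[sid] = inside
            dropped[sid] = len(members) - len(inside)
        return cls(
            sets=harmonized,
            universe=uni,
            names=dict(names or {}),
            out_of_universe=dropped,
        )


def read_gmt(path: str | Path) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Parse a GMT file: one set per line as ``id <TAB> description <TAB> genes...``.

    Returns (set_id -> member list, set_id -> description).
    """
    sets: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected id, description, >=1 gene")
            sid, desc, *genes = parts
            genes = [g for g in genes if g]
            if not genes:
                raise ParseError(f"{path}: line {lineno}: gene set {sid!r} is empty")
            if sid in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set id {sid!r}")
            sets[sid] = genes
            names[sid] = desc
    return sets, names


def fisher_enrichment(
    input_genes: Sequence[str],
    collection: GeneSetCollection,
    fdr_thresh: float = 0.05,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per-set Fisher exact enrichment of ``input_genes`` in the collection.

    Input genes outside the universe are dropped (count reported in
    ``.attrs['input_out_of_universe']``).  Returns one row per set with
    observed / expected counts, direction, raw p, BH FDR and a significance
    flag at ``fdr_thresh``; rows sorted by set id.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValidationError("alternative must be 'two-sided', 'greater' or 'less'")
    input_set = set(input_genes)
    if not input_set:
        raise ValidationError("empty input gene list")
    inside = input_set & collection.universe
    dropped = len(input_set) - len(inside)
    if not inside:
        raise ValidationError("no input gene maps into the universe")

    n_universe = len(collection.universe)
    n_input = len(inside)
    rows = []
    for sid in sorted(collection.sets):
        members = collection.sets[sid]
        n_cat = len(members)
        observed = len(members & inside)
        expected = n_input * n_cat / n_universe
        table = [
            [observed, n_cat - observed],
            [n_input - observed, n_universe - n_cat - n_input + observed],
        ]
        _, p = stats.fisher_exact(table, alternative=alternative)
        direction = "over" if observed > expected else "under" if observed < expected else "none"
        rows.append(
            {
                "set_id": sid,
                "name": collection.names.get(sid, ""),
                "universe_size": n_universe,
                "category_size": n_cat,
                "input_size": n_input,
                "observed": observed,
                "expected": expected,
                "direction": direction,
                "raw_p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["raw_p"].to_numpy())
    out["significant"] = out["fdr"] < fdr_thresh
    out.attrs["input_out_of_universe"] = dropped
    return out
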