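"""Hypergeometric over-representation analysis against GMT gene-set collections."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io import FormatError
from .stats import benjamini_hochberg, hypergeometric_overrep


@dataclass
class GeneSetCollection:
    """term_id -> (term_name, member genes)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (term, description, members...; tab-separated)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno} has {len(fields)} fields, need >= 3")
            term, desc, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                warnings.warn(
                    f"GMT term {term}: deduplicated {len(members) - len(unique)} member(s)",
                    stacklevel=2,
                )
            sets[term] = (desc, unique)
    return GeneSetCollection(sets)


def run_ora(
    query: set[str] | list[str],
    background: set[str] | list[str],
    coll: GeneSetCollection,
    min_set: int = 3,
    max_set: int = 2000,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each term.

    Gene sets are intersected with the background before testing; terms whose
    intersected size falls outside [min_set, max_set] are skipped.  BH across
    tested terms; sorted by adjusted p then term id.
    """
    query = set(query)
    background = set(background)
    stray = query - background
    if stray:
        raise ValueError(
            f"{len(stray)} query gene(s) not in background, e.g. {sorted(stray)[:5]}"
        )
    n_bg = len(background)
    n_query = len(query)
    rows = []
    for term, (name, members) in coll.sets.items():
        in_bg = set(members) & background
        if not (min_set <= len(in_bg) <= max_set):
            continue
        overlap = sorted(query & in_bg)
        p = hypergeometric_overrep(len(overlap), len(in_bg), n_query, n_bg)
        rows.append(
            {
                "term_id": term,
                "term_name": name,
                "k": len(overlap),
                "K": len(in_bg),
                "n": n_query,
                "N": n_bg,
                "p_raw": p,
                "genes": ",".join(overlap),
            }
        )
    out = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p_raw", "genes"]
    )
    if len(out):
        out["p_adj"] = benjamini_hochberg(out["p_raw"].to_numpy())
        out = out.sort_values(["p_adj", "term_id"], ignore_index=True)
    else:
        out["p_adj"] = []
    return out
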