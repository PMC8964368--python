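"""Gene-set over-representation analysis (Fisher's exact test + BH FDR).

Module gene lists are tested against an annotation collection using the
one-sided (over-representation) Fisher's exact test with all genes as the
background universe, and the p-values are corrected per module and per
collection by the Benjamini–Hochberg false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ParseError, ValidationError


@dataclass
class GeneSetCollection:
    """term id -> (description, member genes), plus the background universe."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        if self.universe is None:
            u: set[str] = set()
            for members in self.sets.values():
                u |= members
            self.universe = u
        for term, members in self.sets.items():
            if not members:
                raise ValidationError(f"term {term} has no members")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file (term, description, genes...), deduplicating members.

    The background universe defaults to the union of all members unless one
    is supplied.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            term, desc, *genes = fields
            sets[term] = set(g for g in genes if g)
            descriptions[term] = desc
    return GeneSetCollection(sets, descriptions, universe)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(collection.sets):
            desc = collection.descriptions.get(term, "")
            genes = "\t".join(sorted(collection.sets[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


def fisher_enrichment(
    module_genes, sets: GeneSetCollection, module_label: str = "module"
) -> pd.DataFrame:
    """One-sided over-representation p per term for one module gene list.

    The 2x2 table per term is (k, n-k, K-k, N-n-K+k) with k the overlap,
    n the module size within the universe, K the term size and N the
    universe size; the one-sided p is the upper hypergeometric tail
    P[X >= k].  Genes absent from the universe are excluded and their count
    reported in the ``excluded_genes`` column.  BH q-values are added across
    the terms of this collection.
    """
    module = set(module_genes)
    universe = sets.universe
    in_universe = module & universe
    if not in_universe:
        raise ValidationError("module has no genes in the annotation universe")
    excluded = len(module) - len(in_universe)
    N = len(universe)
    n = len(in_universe)
    rows = []
    for term in sorted(sets.sets):
        members = sets.sets[term] & universe
        K = len(members)
        k = len(in_universe & members)
        # P[X >= k] for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        rows.append((module_label, term, sets.descriptions.get(term, ""),
                     k, K, n, N, p, excluded))
    tab = pd.DataFrame(
        rows,
        columns=["module", "term", "description", "k", "K", "n", "N", "p",
                 "excluded_genes"],
    )
    tab["q"] = bh_fdr(tab["p"].to_numpy())
    return tab


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def top_terms(tab: pd.DataFrame, k: int = 5, fdr_line: float = 0.05) -> pd.DataFrame:
    """Top-k terms by ascending p; ties by larger overlap, then term id.

    Adds a ``significant`` flag at q <= ``fdr_line`` and a 1-based ``rank``.
    """
    if k <= 0:
        raise ConfigError("k must be positive")
    ranked = tab.sort_values(
        by=["p", "k", "term"], ascending=[True, False, True], kind="stable"
    ).head(k).copy()
    ranked["significant"] = ranked["q"] <= fdr_line
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked.reset_index(drop=True)


def enrich_modules(
    partition_members: dict[str, list[str]],
    sets: GeneSetCollection,
    top_k: int = 5,
    fdr_line: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full ORA for every module; FDR is computed per module.

    Returns ``(full_table, top_table)``.
    """
    full, tops = [], []
    for label, genes in partition_members.items():
        tab = fisher_enrichment(genes, sets, module_label=label)
        full.append(tab)
        tops.append(top_terms(tab, k=top_k, fdr_line=fdr_line))
    if not full:
        empty = pd.DataFrame()
        return empty, empty
    return (pd.concat(full, ignore_index=True),
            pd.concat(tops, ignore_index=True))
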