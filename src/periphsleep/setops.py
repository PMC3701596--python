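"""Probe-to-gene collapsing, overlap tests, and gene-set enrichment.

Replaces the external annotation service with a generic one-tailed
Fisher/hypergeometric over-representation test against user-supplied gene
sets (GMT format).  The background defaults to the genes assayed on the
array rather than the genome, matching array-based testing.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffstate import bh_fdr

log = logging.getLogger(__name__)


class GeneSetCollection:
    """Named gene sets with optional descriptions; symbols share one case
    convention (uppercase by default)."""

    def __init__(self, sets: dict, descriptions: dict | None = None,
                 uppercase: bool = True):
        self.uppercase = uppercase
        self.sets = {}
        self.descriptions = {}
        for name, genes in sets.items():
            if name in self.sets:
                raise ValueError(f"duplicate set name {name!r}")
            self.sets[name] = frozenset(self._norm(g) for g in genes)
            self.descriptions[name] = (descriptions or {}).get(name, "")

    def _norm(self, gene: str) -> str:
        return gene.upper() if self.uppercase else gene

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path, uppercase: bool = True) -> GeneSetCollection:
    """Read a GMT file: ``name <TAB> description <TAB> gene1 <TAB> ...``."""
    sets, desc = {}, {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: GMT line has fewer than 3 fields: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
        desc[fields[0]] = fields[1]
    return GeneSetCollection(sets, desc, uppercase=uppercase)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            fh.write("\t".join([name, collection.descriptions.get(name, "")]
                               + sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# Probe -> gene collapsing
# ---------------------------------------------------------------------------

def collapse_probes(results: pd.DataFrame, probe_to_gene: pd.DataFrame,
                    call_columns=None, rule: str = "any") -> pd.DataFrame:
    """Collapse a probe-level boolean call table to unique genes.

    ``probe_to_gene`` has columns ``probe_id`` and ``gene``; duplicate
    (probe, gene) rows are deduplicated with a warning and unmapped probes
    are excluded from the gene level (they remain in the probe-level
    input).  Under ``rule='any'`` a gene carries a call if any of its
    probes does; ``rule='all'`` requires every probe.
    """
    if rule not in ("any", "all"):
        raise ValueError("rule must be 'any' or 'all'")
    mapping = probe_to_gene[["probe_id", "gene"]].dropna()
    if mapping.duplicated().any():
        warnings.warn("duplicate (probe, gene) rows in the annotation; deduplicating")
        mapping = mapping.drop_duplicates()
    if call_columns is None:
        call_columns = [c for c in results.columns if results[c].dtype == bool]
    if not call_columns:
        raise ValueError("no boolean call columns to collapse")
    probe_tab = results[list(call_columns)].copy()
    probe_tab.index.name = "probe_id"
    merged = mapping.merge(probe_tab, on="probe_id", how="inner")
    agg = merged.groupby("gene")[list(call_columns)].agg(rule)
    agg["n_probes"] = merged.groupby("gene").size()
    return agg


# ---------------------------------------------------------------------------
# Overlap and enrichment tests
# ---------------------------------------------------------------------------

def overlap_fisher(list_a, list_b, universe):
    """One-tailed (enrichment) Fisher's exact test of two-list overlap.

    Returns ``(table, odds_ratio, p)`` where ``table`` is the 2x2
    membership count array and ``p = P(X >= observed overlap)`` under the
    hypergeometric null.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    a = set(list_a)
    b = set(list_b)
    if not a <= universe or not b <= universe:
        raise ValueError("both lists must be subsets of the universe")
    k = len(a & b)
    table = np.array([
        [k, len(a) - k],
        [len(b) - k, len(universe) - len(a) - len(b) + k],
    ])
    odds, p = stats.fisher_exact(table, alternative="greater")
    return table, odds, float(p)


def enrich(gene_list, collection: GeneSetCollection, background,
           ease: bool = False, alternative: str = "greater") -> pd.DataFrame:
    """Over-representation of ``gene_list`` in each set of ``collection``.

    Terms are intersected with ``background`` (which must contain the
    list) before testing; terms with no background genes are skipped with
    a log entry.  ``ease=True`` applies the conservative one-hit discount
    (the Fisher tail is evaluated at k-1 hits), an upper bound on the
    enrichment p-value.  Rows are sorted by p; ``q`` is BH over the tested
    terms; ``fold = (k/n) / (K/N)``.
    """
    norm = collection._norm
    bg = {norm(g) for g in background}
    genes = {norm(g) for g in gene_list}
    if not genes <= bg:
        raise ValueError("gene list must be a subset of the background")
    n = len(genes)
    big_n = len(bg)
    rows = []
    for name, members in collection:
        members = members & bg
        big_k = len(members)
        if big_k == 0:
            log.info("term %s has no background genes after intersection; skipped",
                     name)
            continue
        k = len(genes & members)
        k_eff = max(k - 1, 0) if ease else k
        table = [[k_eff, n - k_eff], [big_k - k_eff, big_n - n - big_k + k_eff]]
        _, p = stats.fisher_exact(table, alternative=alternative)
        fold = (k / n) / (big_k / big_n) if n else np.nan
        rows.append({
            "term": name,
            "description": collection.descriptions.get(name, ""),
            "k": k, "n": n, "K": big_k, "N": big_n,
            "p": float(p), "fold": fold,
        })
    out = pd.DataFrame(rows, columns=["term", "description", "k", "n", "K",
                                      "N", "p", "fold"])
    if len(out):
        out["q"] = bh_fdr(np.clip(out["p"].to_numpy(), np.finfo(float).tiny, 1.0))
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        out["q"] = []
    return out
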