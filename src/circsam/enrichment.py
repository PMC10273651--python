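"""GO term enrichment: one-sided Fisher (hypergeometric upper tail) per term
with Benjamini-Hochberg correction.

"Classic" semantics: every term is tested independently of the GO graph
(no elim/weight decorrelation), but gene annotations ARE propagated to
ancestor terms first, using the parent table supplied with the term map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GoAnnotationMap:
    term_genes: dict[str, set[str]]
    term_info: dict[str, tuple[str, str]] = field(default_factory=dict)  # name, namespace
    term_parents: dict[str, list[str]] = field(default_factory=dict)

    def propagate(self) -> "GoAnnotationMap":
        """Copy with each gene annotated to every ancestor of its terms."""
        out = {t: set(g) for t, g in self.term_genes.items()}
        for term, genes in self.term_genes.items():
            for anc in self._ancestors(term):
                out.setdefault(anc, set()).update(genes)
        return GoAnnotationMap(out, dict(self.term_info), dict(self.term_parents))

    def _ancestors(self, term: str) -> set[str]:
        seen: set[str] = set()
        stack = list(self.term_parents.get(term, []))
        while stack:
            t = stack.pop()
            if t and t not in seen:
                seen.add(t)
                stack.extend(self.term_parents.get(t, []))
        return seen


def read_go_map(map_path, terms_path=None) -> GoAnnotationMap:
    """GO map TSV (gene_id, term_id) plus optional term table
    (term_id, name, namespace, parent_ids with comma-separated parents)."""
    df = pd.read_csv(map_path, sep="\t")
    if not {"gene_id", "term_id"} <= set(df.columns):
        raise ValueError("GO map needs gene_id and term_id columns")
    term_genes: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        term_genes.setdefault(str(row.term_id), set()).add(str(row.gene_id))
    info: dict[str, tuple[str, str]] = {}
    parents: dict[str, list[str]] = {}
    if terms_path is not None:
        tdf = pd.read_csv(terms_path, sep="\t").fillna("")
        for row in tdf.itertuples(index=False):
            info[str(row.term_id)] = (str(row.name), str(row.namespace))
            plist = [p for p in str(row.parent_ids).split(",") if p]
            parents[str(row.term_id)] = plist
    return GoAnnotationMap(term_genes, info, parents)


def fisher_enrichment(
    study: set[str],
    universe: set[str],
    go: GoAnnotationMap,
    propagate: bool = True,
) -> pd.DataFrame:
    """Per-term enrichment: k study hits, K universe term genes, n study
    size, N universe size, one-sided hypergeometric p = P(X >= k).

    Terms with no study gene are skipped. ``study`` must lie inside
    ``universe``.
    """
    if not study <= universe:
        raise ValueError("study set is not a subset of the universe")
    gomap = go.propagate() if propagate else go
    n, N = len(study), len(universe)
    rows = []
    for term in sorted(gomap.term_genes):
        members = gomap.term_genes[term] & universe
        k = len(study & members)
        if k == 0:
            continue
        K = len(members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        name, namespace = gomap.term_info.get(term, ("", ""))
        rows.append((term, name, namespace, k, K, n, N, p))
    df = pd.DataFrame(
        rows, columns=["term_id", "name", "namespace", "k", "K", "n", "N", "p"]
    )
    if len(df):
        df["p_adjusted"] = bh_fdr(df["p"].tolist())
    else:
        df["p_adjusted"] = []
    return df


def bh_fdr(pvals) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    for p in pvals:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0,1]")
    if len(pvals) == 0:
        return []
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    return [float(a) for a in adj]


def significant_terms(df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    return df[df["p_adjusted"] < alpha].reset_index(drop=True)
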