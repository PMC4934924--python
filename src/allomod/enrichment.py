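"""Hypergeometric term enrichment of modules against GMT gene-set annotations.

For each annotation term, the p-value is the exact upper-tail
hypergeometric probability of drawing at least the observed overlap when
``|module ∩ background|`` genes are sampled without replacement from a
universe of ``|background|`` genes containing ``|term|`` successes.
Benjamini–Hochberg correction is applied across terms, and a module's
function set F(m) is the set of terms with corrected p below alpha (strict).
An EASE-style conservative variant (overlap decremented by one before the
tail) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationSet",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "hypergeometric_enrich",
    "bh_correct",
    "significant_terms",
    "module_functions",
]


@dataclass
class AnnotationSet:
    """Term -> gene-set mapping over a background universe.

    The background defaults to the union of all term gene sets; intersecting
    it with an analysis network's node list (via :meth:`restricted_to`)
    mirrors the usual enrichment convention of testing against the assayed
    universe rather than the whole annotation database.
    """

    terms: dict[str, frozenset[str]]
    background: frozenset[str] = frozenset()
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.terms = {t: frozenset(g) for t, g in self.terms.items()}
        if not self.background:
            universe: set[str] = set()
            for genes in self.terms.values():
                universe |= genes
            self.background = frozenset(universe)
        else:
            self.background = frozenset(self.background)
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")
            if not genes <= self.background:
                raise ValueError(f"term {term!r} has genes outside the background")

    def restricted_to(self, universe: set[str]) -> "AnnotationSet":
        """Clip background and terms to a gene universe (dropping emptied terms)."""
        bg = self.background & frozenset(universe)
        terms = {t: g & bg for t, g in self.terms.items()}
        terms = {t: g for t, g in terms.items() if g}
        return AnnotationSet(terms=terms, background=bg, descriptions=dict(self.descriptions))


@dataclass
class EnrichmentResult:
    term: str
    sample_count: int
    background_count: int
    p: float
    p_corrected: float
    genes: frozenset[str]


def read_gmt(path: str | Path) -> AnnotationSet:
    """Read gene sets from GMT (term <tab> description <tab> genes...)."""
    terms: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need term, description, >=1 gene")
            terms[fields[0]] = frozenset(g for g in fields[2:] if g)
            descriptions[fields[0]] = fields[1]
    return AnnotationSet(terms=terms, descriptions=descriptions)


def write_gmt(ann: AnnotationSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for term in sorted(ann.terms):
            desc = ann.descriptions.get(term, "")
            fh.write("\t".join([term, desc, *sorted(ann.terms[term])]) + "\n")


def hypergeometric_enrich(
    module_genes: set[str],
    ann: AnnotationSet,
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Score every annotation term against one module's gene set.

    Exact upper tail: p = P(X >= k) with X ~ Hypergeom(M=|background|,
    n=|term|, N=|module ∩ background|) and k the observed overlap.  With
    ``ease=True`` the overlap is decremented by one (k-1, floored at 0)
    before taking the tail, the conservative EASE-score variant.  Corrected
    p-values are Benjamini–Hochberg across all terms in the annotation set.
    """
    sample = set(module_genes) & set(ann.background)
    if not sample:
        raise ValueError(
            f"module {sorted(module_genes)[:5]}... shares no genes with the background"
        )
    m_total = len(ann.background)
    n_sample = len(sample)
    results: list[EnrichmentResult] = []
    for term in sorted(ann.terms):
        term_genes = ann.terms[term]
        overlap = sample & term_genes
        k = len(overlap)
        k_eff = max(k - 1, 0) if ease else k
        # P(X >= k_eff) = sf(k_eff - 1)
        p = float(stats.hypergeom.sf(k_eff - 1, m_total, len(term_genes), n_sample))
        p = min(max(p, 0.0), 1.0)
        results.append(
            EnrichmentResult(
                term=term,
                sample_count=k,
                background_count=len(term_genes),
                p=p,
                p_corrected=np.nan,
                genes=frozenset(overlap),
            )
        )
    corrected = bh_correct([r.p for r in results])
    for r, pc in zip(results, corrected):
        r.p_corrected = pc
    return results


def bh_correct(pvals: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1.

    Order-invariant: values are ranked internally and returned in the input
    order.  Adjusted values are monotone non-decreasing in raw-p rank and
    never smaller than the raw value.
    """
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


def significant_terms(results: list[EnrichmentResult], alpha: float = 0.05) -> frozenset[str]:
    """F(m): terms with corrected p strictly below alpha."""
    return frozenset(r.term for r in results if r.p_corrected < alpha)


def module_functions(
    modules,
    ann: AnnotationSet,
    alpha: float = 0.05,
    ease: bool = False,
) -> dict[str, frozenset[str]]:
    """Map module id -> F(m) for every module in an iterable.

    Modules sharing no genes with the background get F(m) = ∅ rather than
    an error, so uncharacterized modules flow through similarity scoring.
    """
    out: dict[str, frozenset[str]] = {}
    for m in modules:
        try:
            res = hypergeometric_enrich(set(m.nodes), ann, ease=ease)
        except ValueError:
            out[m.id] = frozenset()
            continue
        out[m.id] = significant_terms(res, alpha=alpha)
    return out


def results_to_tsv(results: list[EnrichmentResult], path: str | Path) -> None:
    """Write enrichment results with sample/background counts and p-values."""
    with Path(path).open("w") as fh:
        fh.write("term\tsample_number\tbackground_number\tp_value\tcorrected_p_value\tgenes\n")
        for r in sorted(results, key=lambda r: (r.p, r.term)):
            genes = "|".join(sorted(r.genes))
            fh.write(
                f"{r.term}\t{r.sample_count}\t{r.background_count}\t{r.p:.6g}\t{r.p_corrected:.6g}\t{genes}\n"
            )
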