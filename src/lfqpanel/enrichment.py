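"""Over-representation analysis of a study set against term annotations.

One-sided Fisher's exact test (hypergeometric upper tail) per term, with the
Bonferroni / Holm / Benjamini-Hochberg / Benjamini-Yekutieli correction menu;
BH at 0.05 is the default.  The background population is always an explicit
input — there is no silent default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._errors import ConfigError, ValidationError

_METHODS = {
    "bonferroni": "bonferroni",
    "holm": "holm",
    "bh": "fdr_bh",
    "by": "fdr_by",
}

DEFAULT_METHOD = "bh"


@dataclass
class AnnotationMap:
    term_id: str
    proteins: frozenset
    term_name: str = ""

    def __post_init__(self):
        if not self.proteins:
            raise ValidationError(f"term {self.term_id!r} annotates no proteins")


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # study-set hits
    K: int  # population hits
    n: int  # study size
    N: int  # population size
    p_raw: float
    p_adjusted: float
    method: str


def read_annotations(path, names_path=None) -> list[AnnotationMap]:
    """2-column TSV (term_id, protein) -> AnnotationMap list; an optional
    names file (term_id, term_name) supplies display names."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term_id", "protein"], dtype=str)
    names = {}
    if names_path is not None:
        nd = pd.read_csv(names_path, sep="\t", header=None, names=["term_id", "term_name"], dtype=str)
        names = dict(zip(nd["term_id"], nd["term_name"]))
    return [
        AnnotationMap(term, frozenset(sub["protein"]), names.get(term, ""))
        for term, sub in df.groupby("term_id", sort=True)
    ]


def adjust_p(p_values: Sequence[float], method: str = DEFAULT_METHOD) -> list[float]:
    """Multiple-testing adjustment preserving input order, capped at 1."""
    if method not in _METHODS:
        raise ConfigError(f"unknown correction method {method!r}; choose from {sorted(_METHODS)}")
    p = list(p_values)
    if not p:
        return []
    if any(not 0.0 <= x <= 1.0 for x in p):
        raise ValidationError("p-values must lie in [0, 1]")
    return list(multipletests(p, method=_METHODS[method])[1])


def fisher_ora(
    study: Iterable[str],
    population: Iterable[str],
    annotations: Sequence[AnnotationMap],
    method: str = DEFAULT_METHOD,
) -> list[EnrichmentResult]:
    """One result per term with at least one population hit.

    p_raw is the one-sided (enrichment) Fisher exact p of the 2x2 table
    built from study/population term membership.
    """
    study = set(study)
    population = set(population)
    if not population:
        raise ValidationError("population must be nonempty")
    if not study <= population:
        raise ValidationError("study set must be a subset of the population")
    n, N = len(study), len(population)
    rows = []
    for ann in annotations:
        hits = ann.proteins & population
        K = len(hits)
        if K == 0:
            continue
        k = len(study & hits)
        # upper-tail hypergeometric: P[X >= k]
        p_raw = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((ann, k, K, min(p_raw, 1.0)))
    adjusted = adjust_p([r[3] for r in rows], method)
    return [
        EnrichmentResult(
            term_id=ann.term_id,
            term_name=ann.term_name,
            k=k,
            K=K,
            n=n,
            N=N,
            p_raw=p_raw,
            p_adjusted=p_adj,
            method=method,
        )
        for (ann, k, K, p_raw), p_adj in zip(rows, adjusted)
    ]


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "method": r.method,
            }
            for r in results
        ],
        columns=["term_id", "term_name", "k", "K", "n", "N", "p_raw", "p_adjusted", "method"],
    )
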