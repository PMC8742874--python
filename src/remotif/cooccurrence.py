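"""Gene-level motif-presence statistics and Monte-Carlo expectations.

For each (gene, motif) pair a summary records in which feature classes the
motif occurs; genes are then classified as UTR_only / CDS_only /
UTR_and_CDS / intron_only / none, with an intron flag overlaid on the
exonic classes. Category percentages are compared with the expectation
from random gene sets drawn without replacement from the annotated-gene
universe (150 simulations per set size by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotatedHit
from .core import (
    REGION_3UTR,
    REGION_5UTR,
    REGION_CDS,
    REGION_INTRON,
    GeneAnnotation,
)

logger = logging.getLogger(__name__)

CLASSES = ("UTR_only", "CDS_only", "UTR_and_CDS", "intron_only", "none")


def classify(has_5utr: bool, has_3utr: bool, has_cds: bool, has_intron: bool) -> str:
    """Gene class from per-region motif presence (one class per gene)."""
    utr = has_5utr or has_3utr
    if utr and has_cds:
        return "UTR_and_CDS"
    if utr:
        return "UTR_only"
    if has_cds:
        return "CDS_only"
    if has_intron:
        return "intron_only"
    return "none"


def summarize_genes(ahits: Iterable[AnnotatedHit], ann: GeneAnnotation,
                    motifs: Sequence[str]) -> pd.DataFrame:
    """One row per (gene, motif): region booleans, class, intron flag.

    Genes without hits for a motif get class ``none``; a motif name absent
    from the hits entirely is logged, not an error. Hits are expected to be
    annotated and strand-filtered already.
    """
    flags: dict[tuple[str, str], dict[str, bool]] = {}
    seen_motifs: set[str] = set()
    for a in ahits:
        seen_motifs.add(a.hit.motif_name)
        key = (a.gene_id, a.hit.motif_name)
        f = flags.setdefault(key, dict.fromkeys(
            ("has_5UTR", "has_3UTR", "has_CDS", "has_intron"), False))
        f["has_5UTR"] |= REGION_5UTR in a.regions
        f["has_3UTR"] |= REGION_3UTR in a.regions
        f["has_CDS"] |= REGION_CDS in a.regions
        f["has_intron"] |= REGION_INTRON in a.regions
    for m in motifs:
        if m not in seen_motifs:
            logger.info("motif %s has no annotated hits; all genes class none", m)

    rows = []
    for gene_id in sorted(ann.genes):
        for motif in motifs:
            f = flags.get((gene_id, motif),
                          dict.fromkeys(("has_5UTR", "has_3UTR", "has_CDS", "has_intron"), False))
            cls = classify(f["has_5UTR"], f["has_3UTR"], f["has_CDS"], f["has_intron"])
            rows.append({"gene_id": gene_id, "motif": motif, **f,
                         "cls": cls, "intron_flag": f["has_intron"]})
    return pd.DataFrame(rows)


def _has_motif(summaries: pd.DataFrame, motif: str, scope: str = "any") -> pd.Series:
    """Boolean per gene: does the gene carry the motif under the scope?

    scope 'any' counts any class != none; 'utr_cds' requires an exonic
    (UTR or CDS) instance.
    """
    sub = summaries[summaries["motif"] == motif].set_index("gene_id")
    if scope == "any":
        return sub["cls"] != "none"
    if scope == "utr_cds":
        return sub["has_5UTR"] | sub["has_3UTR"] | sub["has_CDS"]
    raise ValueError(f"unknown scope {scope!r}")


@dataclass
class CategoryStat:
    """Observed percent of genes in a category carrying a motif."""

    category_name: str
    n_genes: int
    percent_with_motif: float
    breakdown: dict[str, float] = field(default_factory=dict)
    percent_intron_flag: float = 0.0


def category_percent(summaries: pd.DataFrame, gene_set: Iterable[str],
                     motif: str, category_name: str = "category") -> CategoryStat:
    """Percent of genes in a set whose class is not ``none``, with the
    per-class breakdown. Genes absent from the summaries are logged and
    ignored."""
    gene_set = set(gene_set)
    sub = summaries[(summaries["motif"] == motif)
                    & summaries["gene_id"].isin(gene_set)]
    missing = gene_set - set(sub["gene_id"])
    if missing:
        logger.warning("%d genes in category %s not in annotation; ignored",
                       len(missing), category_name)
    n = len(sub)
    if n == 0:
        raise ValueError(f"category {category_name!r} has no annotated genes")
    counts = sub["cls"].value_counts()
    breakdown = {c: 100.0 * counts.get(c, 0) / n for c in CLASSES if c != "none"}
    return CategoryStat(
        category_name=category_name,
        n_genes=n,
        percent_with_motif=100.0 * (sub["cls"] != "none").sum() / n,
        breakdown=breakdown,
        percent_intron_flag=100.0 * sub["intron_flag"].sum() / n,
    )


@dataclass
class ExpectedStat:
    """Random-gene-set expectation of percent-with-motif."""

    set_sizes: list[int]
    n_sims: int
    mean_percent: dict[int, float]
    sd_percent: dict[int, float]
    seed: int | None


def expected_percent(summaries: pd.DataFrame, motif: str,
                     set_sizes: Sequence[int] = (100, 500, 1000, 3000),
                     n_sims: int = 150, seed: int | None = None,
                     scope: str = "any",
                     rng: np.random.Generator | None = None) -> ExpectedStat:
    """Expected percent of genes with a motif in random gene sets.

    For each set size, draws ``n_sims`` subsets without replacement from
    all annotated genes and averages the percent carrying the motif.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    has = _has_motif(summaries, motif, scope).to_numpy()
    pop = len(has)
    mean_percent: dict[int, float] = {}
    sd_percent: dict[int, float] = {}
    for size in set_sizes:
        if size > pop:
            raise ValueError(f"set size {size} exceeds population {pop}")
        percents = np.empty(n_sims)
        for i in range(n_sims):
            idx = rng.choice(pop, size=size, replace=False)
            percents[i] = 100.0 * has[idx].mean()
        mean_percent[size] = float(percents.mean())
        sd_percent[size] = float(percents.std(ddof=1)) if n_sims > 1 else 0.0
    return ExpectedStat(list(set_sizes), n_sims, mean_percent, sd_percent, seed)


def cooccurrence_fraction(summaries_a: pd.DataFrame, summaries_b: pd.DataFrame,
                          motif_a: str, motif_b: str,
                          gene_set: Iterable[str] | None = None,
                          denominator: str = "either",
                          scope: str = "any") -> float:
    """Percent of genes carrying instances of both motifs.

    ``denominator`` 'either' restricts to genes with at least one motif of
    either factor; 'all' uses the whole gene set.
    """
    has_a = _has_motif(summaries_a, motif_a, scope)
    has_b = _has_motif(summaries_b, motif_b, scope)
    has_a, has_b = has_a.align(has_b, fill_value=False)
    if gene_set is not None:
        keep = has_a.index.isin(set(gene_set))
        has_a, has_b = has_a[keep], has_b[keep]
    if denominator == "either":
        denom = has_a | has_b
    elif denominator == "all":
        denom = pd.Series(True, index=has_a.index)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    n = int(denom.sum())
    if n == 0:
        raise ValueError("empty denominator gene set")
    return float(100.0 * (has_a & has_b)[denom].sum() / n)
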