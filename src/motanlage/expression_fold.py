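"""Signed fold-change table for candidate cytoskeletal genes.

Per gene: optional replicate-consistency filtering, group means, and a signed
fold change of MUT relative to WT using the negative-reciprocal convention
(increase -> alt/ref, decrease -> -(ref/alt), so |fold| >= 1).  A packaged
reference table of published group means for 38 candidate genes ships with
the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_away_from_zero

__all__ = [
    "GeneRecord",
    "FoldTable",
    "signed_fold",
    "replicate_filter",
    "build_fold_table",
    "rank_candidates",
    "load_reference_means",
    "CATEGORIES",
]

CATEGORIES = ("actin", "microtubule", "adhesion", "signaling")


def signed_fold(ref_mean: float, alt_mean: float) -> float:
    """alt/ref when alt >= ref, else -(ref/alt); |result| >= 1."""
    if ref_mean <= 0 or alt_mean <= 0:
        raise ValueError(
            f"means must be positive, got ref={ref_mean}, alt={alt_mean}"
        )
    if alt_mean >= ref_mean:
        return alt_mean / ref_mean
    return -(ref_mean / alt_mean)


def replicate_filter(
    values: Sequence[float], f_max: float = 0.5, eps: float = 1e-12
) -> tuple[list[float], int | None]:
    """Drop at most one of three replicates that is inconsistent with the rest.

    Replicate i is a candidate for flagging iff
    ``|values[i] - median| > f_max * max(median, eps)``; if several qualify,
    only the worst offender is dropped.  Returns (kept values, flagged index
    or None).
    """
    vals = list(map(float, values))
    if len(vals) != 3:
        raise ValueError(f"expected exactly 3 replicates, got {len(vals)}")
    med = float(np.median(vals))
    limit = f_max * max(med, eps)
    deviations = [abs(v - med) for v in vals]
    worst = int(np.argmax(deviations))
    if deviations[worst] > limit:
        kept = [v for i, v in enumerate(vals) if i != worst]
        return kept, worst
    return vals, None


@dataclass(frozen=True)
class GeneRecord:
    gene: str
    category: str
    means: tuple[float, float, float]  # (wt, het, mut)
    sds: tuple[float, float, float]
    fold: float
    flagged_replicates: Mapping[str, int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category {self.category!r} not one of {CATEGORIES}"
            )
        if abs(self.fold) < 1.0 - 1e-9:
            raise ValueError(f"|fold| must be >= 1, got {self.fold}")


@dataclass(frozen=True)
class FoldTable:
    records: tuple[GeneRecord, ...]
    rounding: int = 1

    def rounded_folds(self) -> dict[str, float]:
        """Per-gene fold rounded half-away-from-zero at table precision."""
        return {
            r.gene: round_half_away_from_zero(r.fold, self.rounding)
            for r in self.records
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": r.gene,
                "category": r.category,
                "wt_mean": r.means[0],
                "het_mean": r.means[1],
                "mut_mean": r.means[2],
                "wt_sd": r.sds[0],
                "het_sd": r.sds[1],
                "mut_sd": r.sds[2],
                "fold": round_half_away_from_zero(r.fold, self.rounding),
                "flagged": ";".join(
                    f"{g}:{i}"
                    for g, i in r.flagged_replicates.items()
                    if i is not None
                ),
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)


_GENOTYPES = ("WT", "HET", "MUT")


def build_fold_table(
    replicates: pd.DataFrame,
    annotations: Mapping[str, str],
    f_max: float = 0.5,
    rounding: int = 1,
    apply_filter: bool = True,
) -> FoldTable:
    """Fold table from a long-format replicate table.

    ``replicates`` needs columns gene, genotype, replicate, value (as produced
    by :func:`motanlage.synthetic_data.simulate_expression`).  Per gene and
    genotype the replicate filter drops at most one inconsistent value before
    means/sds; the fold is signed_fold(wt_mean, mut_mean).  Records are sorted
    within category by descending fold, ties stable.
    """
    required = {"gene", "genotype", "replicate", "value"}
    missing = required - set(replicates.columns)
    if missing:
        raise ValueError(f"replicate table missing columns {sorted(missing)}")

    records = []
    for gene, sub in replicates.groupby("gene", sort=False):
        means, sds, flagged = {}, {}, {}
        for genotype in _GENOTYPES:
            vals = (
                sub[sub["genotype"] == genotype]
                .sort_values("replicate")["value"]
                .to_list()
            )
            if not vals:
                raise ValueError(f"gene {gene!r} missing genotype {genotype}")
            if apply_filter and len(vals) == 3:
                kept, idx = replicate_filter(vals, f_max=f_max)
            else:
                kept, idx = vals, None
            means[genotype] = float(np.mean(kept))
            sds[genotype] = float(np.std(kept, ddof=1)) if len(kept) > 1 else 0.0
            flagged[genotype] = idx
        category = annotations.get(gene)
        if category is None:
            raise KeyError(f"no category annotation for gene {gene!r}")
        records.append(
            GeneRecord(
                gene=str(gene),
                category=category,
                means=(means["WT"], means["HET"], means["MUT"]),
                sds=(sds["WT"], sds["HET"], sds["MUT"]),
                fold=signed_fold(means["WT"], means["MUT"]),
                flagged_replicates=flagged,
            )
        )
    records.sort(key=lambda r: (CATEGORIES.index(r.category), -r.fold))
    return FoldTable(records=tuple(records), rounding=rounding)


def rank_candidates(
    table: FoldTable, top_n: int
) -> dict[str, list[GeneRecord]]:
    """Per-category top-n records by |fold|, ties broken alphabetically."""
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    out: dict[str, list[GeneRecord]] = {}
    for cat in CATEGORIES:
        members = [r for r in table.records if r.category == cat]
        members.sort(key=lambda r: (-abs(r.fold), r.gene))
        if members:
            out[cat] = members[:top_n]
    return out


def load_reference_means() -> pd.DataFrame:
    """Packaged reference table of published candidate-gene group means.

    Columns: gene, category, wt_mean, wt_sd, het_mean, het_sd, mut_mean,
    mut_sd, reported_fold.
    """
    ref = resources.files("motanlage.data").joinpath("candidate_gene_means.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
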