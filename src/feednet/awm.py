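"""Association weight matrix (AWM) construction and gene selection.

The AWM condenses multi-trait GWAS summary statistics around a key
phenotype into a variant x trait matrix of z-scores, then reduces it
to one representative SNP per gene:

1. *Key SNPs*: variants with P <= ``p_threshold`` (default 0.001) for
   the key trait seed the matrix.
2. *Trait retention*: a non-key trait is kept if the Pearson
   correlation of its z-scores with the key trait's, over the key
   SNPs, satisfies |r| >= ``r_threshold`` (default 0.25).
3. *Secondary SNPs*: variants not selected in step 1 are recruited if
   they reach P <= ``p_threshold`` for at least ``min_other_traits``
   (default 2) retained non-key traits.
4. *Gene reduction*: each SNP is assigned to the gene whose body
   contains it (strictly within; overlaps resolved by nearest gene
   midpoint); per gene, the SNP associated with the largest number of
   traits wins, ties broken by the lowest cumulated P-value over its
   associated traits, then by genomic position.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ValidationError

__all__ = [
    "AWMConfig",
    "AWMatrix",
    "build_awm",
    "assign_genes",
    "select_snp_per_gene",
    "summarize_network",
]

logger = logging.getLogger(__name__)


@dataclass
class AWMConfig:
    key_trait: str = "RFI"
    p_threshold: float = 0.001
    r_threshold: float = 0.25
    min_other_traits: int = 2
    #: 'sum' = arithmetic sum of raw P over associated traits;
    #: 'neglog10' = maximize the summed -log10 P instead
    cum_p_mode: str = "sum"

    def __post_init__(self):
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValidationError("p_threshold must be in (0, 1]")
        if not (0.0 < self.r_threshold <= 1.0):
            raise ValidationError("r_threshold must be in (0, 1]")
        if self.min_other_traits < 1:
            raise ValidationError("min_other_traits must be >= 1")
        if self.cum_p_mode not in ("sum", "neglog10"):
            raise ValidationError("cum_p_mode must be 'sum' or 'neglog10'")


@dataclass
class AWMatrix:
    """Selected-variant x retained-trait z-score matrix.

    ``z`` and ``p`` are DataFrames indexed by variant_id with one
    column per retained trait; ``assoc`` flags ``p <= p_threshold``;
    ``origin`` tags each row 'key' or 'secondary'. ``variants`` carries
    chrom/pos metadata for the rows.
    """

    key_trait: str
    z: pd.DataFrame
    p: pd.DataFrame
    assoc: pd.DataFrame
    origin: pd.Series
    variants: pd.DataFrame
    retained_traits: list = field(default_factory=list)
    trait_correlations: dict = field(default_factory=dict)

    @property
    def n_variants(self) -> int:
        return len(self.z)

    def is_empty(self) -> bool:
        return len(self.z) == 0


def build_awm(results: dict, cfg: AWMConfig) -> AWMatrix:
    """Three-stage AWM construction from per-trait GWAS tables.

    ``results`` maps trait label -> GWAS result DataFrame (columns
    ``variant_id, chrom, pos, z, p``); all tables must cover the same
    variant universe. Returns an empty matrix (with a warning) when no
    variant passes the key-trait threshold.
    """
    if cfg.key_trait not in results:
        raise ValidationError(f"key trait {cfg.key_trait!r} not in results")
    key = cfg.key_trait
    traits = list(results)
    base = results[key].set_index("variant_id")
    universe = base.index
    zmat = pd.DataFrame(index=universe)
    pmat = pd.DataFrame(index=universe)
    for t in traits:
        df = results[t].set_index("variant_id")
        if not df.index.equals(universe):
            if set(df.index) != set(universe):
                raise ValidationError(
                    f"trait {t!r} covers a different variant universe"
                )
            df = df.reindex(universe)
        zmat[t] = df["z"]
        pmat[t] = df["p"]

    stage1 = pmat.index[pmat[key] <= cfg.p_threshold]
    if len(stage1) == 0:
        warnings.warn("no variant passes the key-trait P threshold; AWM is empty")
        empty = pd.DataFrame(columns=[key])
        return AWMatrix(
            key_trait=key,
            z=empty.copy(),
            p=empty.copy(),
            assoc=empty.astype(bool),
            origin=pd.Series(dtype=object),
            variants=base.iloc[0:0][["chrom", "pos"]],
            retained_traits=[key],
        )

    # stage 2: retain traits co-associated with the key over stage-1 rows
    corr = {}
    retained = [key]
    zk = zmat.loc[stage1, key].to_numpy()
    for t in traits:
        if t == key:
            continue
        zt = zmat.loc[stage1, t].to_numpy()
        if len(stage1) < 2 or np.std(zk) == 0 or np.std(zt) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(zk, zt)[0, 1])
        corr[t] = r
        if np.isfinite(r) and abs(r) >= cfg.r_threshold:
            retained.append(t)
    non_key = [t for t in retained if t != key]

    # stage 3: recruit variants hitting >= min_other_traits retained non-key traits
    rest = pmat.index.difference(stage1, sort=False)
    if non_key:
        hits = (pmat.loc[rest, non_key] <= cfg.p_threshold).sum(axis=1)
        stage3 = rest[hits >= cfg.min_other_traits]
    else:
        stage3 = rest[0:0]

    rows = universe[universe.isin(set(stage1) | set(stage3))]  # genome order
    origin = pd.Series(
        np.where(rows.isin(set(stage1)), "key", "secondary"), index=rows
    )
    z = zmat.loc[rows, retained]
    p = pmat.loc[rows, retained]
    assoc = p <= cfg.p_threshold
    logger.info(
        "AWM[%s]: %d key + %d secondary variants, traits retained: %s",
        key, (origin == "key").sum(), (origin == "secondary").sum(), retained,
    )
    return AWMatrix(
        key_trait=key,
        z=z,
        p=p,
        assoc=assoc,
        origin=origin,
        variants=base.loc[rows, ["chrom", "pos"]],
        retained_traits=retained,
        trait_correlations=corr,
    )


def assign_genes(variants: pd.DataFrame, annotation: pd.DataFrame) -> pd.Series:
    """Map each variant to the gene body containing it.

    A variant maps to gene g iff ``start <= pos <= end`` on the same
    chromosome (1-based closed coordinates). Variants inside no gene
    are absent from the returned Series. When gene bodies overlap, the
    gene whose midpoint is nearest the variant wins (ties: smaller
    start, then gene_id).
    """
    vc = set(variants["chrom"].astype(str))
    ac = set(annotation["chrom"].astype(str))
    if not (vc & ac):
        raise ValidationError(
            f"no shared chromosome labels between variants ({sorted(vc)[:5]}...) "
            f"and annotation ({sorted(ac)[:5]}...)"
        )
    out = {}
    ann_by_chrom = dict(tuple(annotation.groupby(annotation["chrom"].astype(str))))
    for chrom, sub in variants.groupby(variants["chrom"].astype(str)):
        genes = ann_by_chrom.get(chrom)
        if genes is None:
            continue
        starts = genes["start"].to_numpy()
        ends = genes["end"].to_numpy()
        mids = (starts + ends) / 2.0
        gids = genes["gene_id"].to_numpy()
        order = np.argsort(starts, kind="mergesort")
        starts_s, ends_s = starts[order], ends[order]
        max_len = int((ends_s - starts_s).max()) if len(starts_s) else 0
        for vid, pos in zip(sub["variant_id"], sub["pos"]):
            # candidate genes: start in (pos - max_len, pos]
            hi = np.searchsorted(starts_s, pos, side="right")
            lo = np.searchsorted(starts_s, pos - max_len, side="left")
            cand = order[lo:hi][ends_s[lo:hi] >= pos]
            if len(cand) == 0:
                continue
            if len(cand) == 1:
                out[vid] = gids[cand[0]]
            else:
                d = np.abs(mids[cand] - pos)
                best = sorted(
                    zip(d, starts[cand], gids[cand], cand), key=lambda t: t[:3]
                )[0]
                out[vid] = best[2]
    return pd.Series(out, name="gene_id")


def select_snp_per_gene(awm: AWMatrix, gene_map: pd.Series, cum_p_mode: str = "sum"):
    """One representative SNP per gene.

    Among a gene's AWM variants, pick the one associated with the most
    traits; break ties by the lowest cumulated P-value over the
    variant's associated traits (``cum_p_mode='sum'``, the default; with
    ``'neglog10'`` the summed -log10 P is maximized instead), then by
    genomic position. Returns ``(gene_table, unassigned_variant_ids)``;
    the gene table has one row per gene with the chosen variant, its
    associated traits and the cumulated P.
    """
    if cum_p_mode not in ("sum", "neglog10"):
        raise ValidationError("cum_p_mode must be 'sum' or 'neglog10'")
    if awm.is_empty():
        raise ValidationError("AWM is empty; nothing to select")
    rows = awm.z.index
    assigned = gene_map.reindex(rows)
    unassigned = rows[assigned.isna()].tolist()

    records = []
    for gene, vids in assigned.dropna().groupby(assigned.dropna()).groups.items():
        best = None
        for vid in vids:
            mask = awm.assoc.loc[vid]
            traits = [t for t in awm.retained_traits if mask[t]]
            n_tr = len(traits)
            pvals = awm.p.loc[vid, traits]
            cum_p = float(pvals.sum())
            if cum_p_mode == "sum":
                rank_cum = cum_p
            else:
                rank_cum = -float(-np.log10(pvals).sum())
            chrom = awm.variants.loc[vid, "chrom"]
            pos = int(awm.variants.loc[vid, "pos"])
            try:
                ckey = float(chrom)
            except (TypeError, ValueError):
                ckey = float("inf")
            key = (-n_tr, rank_cum, ckey, pos)
            if best is None or key < best[0]:
                best = (key, vid, n_tr, traits, cum_p, chrom, pos)
        _, vid, n_tr, traits, cum_p, chrom, pos = best
        records.append(
            {
                "gene_id": gene,
                "variant_id": vid,
                "chrom": chrom,
                "pos": pos,
                "n_traits_associated": n_tr,
                "traits": ",".join(traits),
                "cum_p": cum_p,
                "origin": awm.origin.loc[vid],
            }
        )
    table = pd.DataFrame.from_records(
        records,
        columns=[
            "gene_id", "variant_id", "chrom", "pos",
            "n_traits_associated", "traits", "cum_p", "origin",
        ],
    )
    table = table.sort_values("gene_id", kind="mergesort").reset_index(drop=True)
    return table, unassigned


def summarize_network(selection: pd.DataFrame, key: str) -> dict:
    """Gene counts in the three headline categories plus per-trait counts.

    Categories partition the gene table exactly:
    key-trait-only + key-and-other + other-traits-only = total.
    """
    if len(selection) == 0:
        return {
            "key_trait": key,
            "n_genes_total": 0,
            "n_key_only": 0,
            "n_key_and_other": 0,
            "n_other_only": 0,
            "genes_per_trait": {},
        }
    trait_sets = selection["traits"].map(
        lambda s: frozenset(x for x in str(s).split(",") if x)
    )
    has_key = trait_sets.map(lambda ts: key in ts)
    n_traits = trait_sets.map(len)
    n_key_only = int((has_key & (n_traits == 1)).sum())
    n_key_and_other = int((has_key & (n_traits > 1)).sum())
    n_other_only = int((~has_key).sum())
    per_trait = {}
    for ts in trait_sets:
        for t in ts:
            per_trait[t] = per_trait.get(t, 0) + 1
    return {
        "key_trait": key,
        "n_genes_total": int(len(selection)),
        "n_key_only": n_key_only,
        "n_key_and_other": n_key_and_other,
        "n_other_only": n_other_only,
        "genes_per_trait": dict(sorted(per_trait.items())),
    }
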