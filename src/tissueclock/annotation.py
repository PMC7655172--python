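"""Genomic feature annotation of CpGs and GREAT-style gene regulatory domains.

Feature conventions follow the standard CpG-annotation framework: CpG
islands are taken as given (BED input); shores are the 2 kb flanks of each
island with all island bases subtracted; promoters are the <1 kb strand-aware
window upstream of the TSS. A CpG is a 1-based point, converted to a
length-1 half-open interval for overlap tests; all intervals are 0-based
half-open (BED convention).

Gene regulatory domains use the "basal plus extension" association rule:
basal = 5 kb upstream / 1 kb downstream of the TSS (strand-aware); extended
= basal grown in both directions up to 1 Mb, stopping at the nearest
neighboring gene's basal-domain boundary. Region-level enrichment of a CpG
selection against a background panel is an upper-tail binomial test on the
fraction of background loci covered by the domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

FEATURE_CLASSES = (
    "cpg_island", "shore", "promoter", "five_utr", "exon", "intron",
    "cds", "three_utr", "enhancer",
)

# primary-class priority for a CpG overlapping several features
DEFAULT_PRIORITY = (
    "cpg_island", "shore", "promoter", "five_utr", "three_utr", "cds",
    "exon", "intron", "enhancer", "intergenic",
)

SHORE_FLANK = 2_000
PROMOTER_WINDOW = 1_000
BASAL_UPSTREAM = 5_000
BASAL_DOWNSTREAM = 1_000
MAX_EXTENSION = 1_000_000


@dataclass
class FeatureAnnotation:
    """A set of classified genomic intervals (0-based half-open).

    ``table`` columns: chrom, start, end, feature_class, name.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        if len(t):
            if (t["start"] >= t["end"]).any():
                bad = t[t["start"] >= t["end"]].iloc[0]
                raise ValueError(f"empty/inverted interval {bad['chrom']}:{bad['start']}-{bad['end']}")
            unknown = set(t["feature_class"]) - set(FEATURE_CLASSES)
            if unknown:
                raise ValueError(f"unknown feature class(es): {sorted(unknown)}")

    @classmethod
    def empty(cls) -> "FeatureAnnotation":
        return cls(pd.DataFrame(columns=["chrom", "start", "end", "feature_class", "name"]))

    def concat(self, other: "FeatureAnnotation") -> "FeatureAnnotation":
        return FeatureAnnotation(
            pd.concat([self.table, other.table], ignore_index=True)
        )

    def classes_at(self, chrom: str, pos: int) -> set[str]:
        """Feature classes overlapping the 1-based point ``pos``."""
        p0 = pos - 1
        t = self.table
        hit = t[(t["chrom"] == chrom) & (t["start"] <= p0) & (p0 < t["end"])]
        return set(hit["feature_class"])


def read_bed_features(path, feature_class: str | None = None) -> FeatureAnnotation:
    """Read a BED file (>= 3 columns) of features.

    If ``feature_class`` is given, every interval gets that class; otherwise
    column 4 must carry the class name.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=range(4) if feature_class is None else range(3))
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    if feature_class is None:
        df["feature_class"] = df["name"]
    else:
        df["feature_class"] = feature_class
        df["name"] = feature_class
    return FeatureAnnotation(df[["chrom", "start", "end", "feature_class", "name"]])


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int  # 1-based position of the transcription start site

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss < 1:
            raise ValueError(f"gene {self.gene_id}: tss must be >= 1")


def read_genes_tsv(path) -> list[GeneModel]:
    """Read a gene table (columns gene_id, chrom, strand, tss)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    return [
        GeneModel(r.gene_id, r.chrom, r.strand, int(r.tss)) for r in df.itertuples()
    ]


# ---- interval helpers -----------------------------------------------------------


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _subtract(iv: tuple[int, int], cuts: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """iv minus the union of cuts (all half-open)."""
    pieces = [iv]
    for cs, ce in cuts:
        nxt = []
        for s, e in pieces:
            if ce <= s or cs >= e:
                nxt.append((s, e))
                continue
            if cs > s:
                nxt.append((s, cs))
            if ce < e:
                nxt.append((ce, e))
        pieces = nxt
    return pieces


def derive_shores(islands: FeatureAnnotation,
                  chrom_sizes: dict[str, int] | None = None) -> FeatureAnnotation:
    """2 kb flanks of each CpG island, minus all island bases.

    Flanks are clipped to [0, chromosome size] when sizes are supplied.
    """
    rows = []
    t = islands.table
    by_chrom = {c: _merge(list(zip(g["start"], g["end"]))) for c, g in t.groupby("chrom")}
    for r in t.itertuples():
        bound = chrom_sizes.get(r.chrom) if chrom_sizes else None
        for s, e in ((r.start - SHORE_FLANK, r.start), (r.end, r.end + SHORE_FLANK)):
            s = max(s, 0)
            if bound is not None:
                e = min(e, bound)
            if s >= e:
                continue
            for ps, pe in _subtract((s, e), by_chrom[r.chrom]):
                rows.append({"chrom": r.chrom, "start": ps, "end": pe,
                             "feature_class": "shore", "name": f"shore:{r.name}"})
    if not rows:
        return FeatureAnnotation.empty()
    merged = []
    df = pd.DataFrame(rows)
    for chrom, g in df.groupby("chrom"):
        for s, e in _merge(list(zip(g["start"], g["end"]))):
            merged.append({"chrom": chrom, "start": s, "end": e,
                           "feature_class": "shore", "name": "shore"})
    return FeatureAnnotation(pd.DataFrame(merged))


def derive_promoters(genes: list[GeneModel],
                     chrom_sizes: dict[str, int] | None = None) -> FeatureAnnotation:
    """Strand-aware <1 kb upstream promoter window per TSS.

    Plus strand: the half-open 1,000-base window ending at the TSS;
    minus strand: the mirror window on the other side.
    """
    rows = []
    for g in genes:
        tss0 = g.tss - 1
        if g.strand == "+":
            s, e = tss0 - PROMOTER_WINDOW, tss0
        else:
            s, e = tss0 + 1, tss0 + 1 + PROMOTER_WINDOW
        s = max(s, 0)
        if chrom_sizes and g.chrom in chrom_sizes:
            e = min(e, chrom_sizes[g.chrom])
        if s < e:
            rows.append({"chrom": g.chrom, "start": s, "end": e,
                         "feature_class": "promoter", "name": g.gene_id})
    if not rows:
        return FeatureAnnotation.empty()
    return FeatureAnnotation(pd.DataFrame(rows))


def classify_cpg(locus, ann: FeatureAnnotation,
                 priority: tuple = DEFAULT_PRIORITY) -> tuple[set[str], str]:
    """All overlapping feature classes plus the single primary class.

    A locus overlapping nothing is intergenic. Primary class = first hit in
    the priority order; stable under annotation re-ordering.
    """
    classes = ann.classes_at(locus.chrom, locus.pos)
    if not classes:
        return {"intergenic"}, "intergenic"
    primary = next(c for c in priority if c in classes)
    return classes, primary


def feature_distribution(loci, ann: FeatureAnnotation,
                         priority: tuple = DEFAULT_PRIORITY) -> pd.DataFrame:
    """Counts and fractions of primary feature classes over a locus list."""
    if not len(loci):
        return pd.DataFrame(columns=["feature_class", "count", "fraction"])
    counts: dict[str, int] = {}
    for locus in loci:
        _, primary = classify_cpg(locus, ann, priority)
        counts[primary] = counts.get(primary, 0) + 1
    total = sum(counts.values())
    df = pd.DataFrame(
        {"feature_class": list(counts), "count": list(counts.values())}
    ).sort_values("count", ascending=False, kind="stable", ignore_index=True)
    df["fraction"] = df["count"] / total
    return df


# ---- regulatory domains ---------------------------------------------------------


@dataclass
class RegulatoryDomainSet:
    """Per-gene basal + extended regulatory intervals (0-based half-open)."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def genes_covering(self, chrom: str, pos: int) -> list[str]:
        """Gene ids whose extended domain covers the 1-based point ``pos``."""
        p0 = pos - 1
        t = self.table
        if not len(t):
            return []
        hit = t[(t["chrom"] == chrom) & (t["ext_start"] <= p0) & (p0 < t["ext_end"])]
        return hit["gene_id"].tolist()

    def covers(self, chrom: str, pos: int) -> bool:
        return bool(self.genes_covering(chrom, pos))

    def subset(self, gene_ids) -> "RegulatoryDomainSet":
        keep = self.table[self.table["gene_id"].isin(set(gene_ids))]
        return RegulatoryDomainSet(keep.reset_index(drop=True), self.chrom_sizes)


def build_regulatory_domains(genes: list[GeneModel],
                             chrom_sizes: dict[str, int]) -> RegulatoryDomainSet:
    """Basal-plus-extension regulatory domains.

    basal: 5 kb upstream / 1 kb downstream of the TSS (strand-aware);
    extended: basal grown up to 1 Mb per side, stopping at the nearest
    neighboring gene's basal boundary; everything clipped to the chromosome.
    """
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids).value_counts()
        raise ValueError(f"duplicate gene id(s): {list(dup[dup > 1].index)}")
    rows = []
    for g in genes:
        tss0 = g.tss - 1
        if g.strand == "+":
            bs, be = tss0 - BASAL_UPSTREAM, tss0 + BASAL_DOWNSTREAM
        else:
            bs, be = tss0 - BASAL_DOWNSTREAM + 1, tss0 + BASAL_UPSTREAM + 1
        size = chrom_sizes.get(g.chrom)
        if size is None:
            raise ValueError(f"no chromosome size for {g.chrom}")
        bs, be = max(bs, 0), min(be, size)
        rows.append({"gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
                     "tss": g.tss, "basal_start": bs, "basal_end": be})
    df = pd.DataFrame(rows)
    ext_start, ext_end = [], []
    for r in df.itertuples():
        size = chrom_sizes[r.chrom]
        others = df[(df["chrom"] == r.chrom) & (df["gene_id"] != r.gene_id)]
        left = max(r.basal_start - MAX_EXTENSION, 0)
        right = min(r.basal_end + MAX_EXTENSION, size)
        for o in others.itertuples():
            if o.basal_start < r.basal_start:  # left neighbor
                left = max(left, min(o.basal_end, r.basal_start))
            if o.basal_end > r.basal_end:      # right neighbor
                right = min(right, max(o.basal_start, r.basal_end))
        ext_start.append(left)
        ext_end.append(right)
    df["ext_start"] = ext_start
    df["ext_end"] = ext_end
    return RegulatoryDomainSet(df, dict(chrom_sizes))


def binomial_region_enrichment(selected, background,
                               domains_for_term: RegulatoryDomainSet) -> dict:
    """Region-level binomial enrichment of a CpG selection in a domain set.

    p_hit = fraction of background loci inside any domain of the term's
    genes; k = selected loci inside; p_value = P(X >= k | n, p_hit) for
    X ~ Binomial(n = |selected|, p_hit). ``selected`` must be a subset of
    ``background`` (both lists of CpGLocus).
    """
    bg_ids = {l.id for l in background}
    stray = [l.id for l in selected if l.id not in bg_ids]
    if stray:
        raise ValueError(f"selected loci not in background: {stray[:5]}")
    hit_bg = sum(domains_for_term.covers(l.chrom, l.pos) for l in background)
    p_hit = hit_bg / len(background) if background else 0.0
    k = sum(domains_for_term.covers(l.chrom, l.pos) for l in selected)
    n = len(selected)
    if p_hit == 0.0 and k > 0:
        raise ValueError("selected loci hit domains but no background locus does")
    p_value = 1.0 if k == 0 else float(stats.binom.sf(k - 1, n, p_hit))
    return {"k": int(k), "n": int(n), "p_hit": float(p_hit), "p_value": p_value}
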