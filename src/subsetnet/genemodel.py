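"""Chimeric gene models and alignment-interval counting.

A chimeric gene model is the per-gene union of all protein-coding
transcripts' exons.  Counting follows intersection-nonempty semantics:
for each alignment interval, the gene sets of the feature-covered bases
are intersected (bases touching no exon are ignored); the read is counted
for the gene iff that intersection names exactly one gene.  Multi-mapped
reads (multiplicity > 1) and reads resolving to several genes are
discarded.  Strand is ignored (unstranded protocol); all coordinates are
0-based half-open internally, converted from GTF (1-based closed) at the
reader boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from subsetnet.config import FormatError

log = logging.getLogger(__name__)

EXON_COLUMNS = ["gene_id", "transcript_id", "chrom", "start", "end", "strand", "biotype"]


def validate_exon_table(exons: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EXON_COLUMNS if c not in exons.columns]
    if missing:
        raise FormatError(f"exon table missing columns: {missing}")
    bad = exons[exons["end"] <= exons["start"]]
    if len(bad):
        r = bad.iloc[0]
        raise FormatError(
            f"exon record with end <= start: gene {r['gene_id']} "
            f"transcript {r['transcript_id']} {r['chrom']}:{r['start']}-{r['end']}"
        )
    return exons


def read_exon_tsv(path) -> pd.DataFrame:
    return validate_exon_table(pd.read_csv(path, sep="\t"))


def read_gtf(path) -> pd.DataFrame:
    """Read exon records from a GTF file into an ExonTable.

    Uses gffutils; expects attribute keys gene_id, transcript_id and
    gene_biotype.  GTF 1-based closed coordinates become 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    rows = []
    for ex in db.features_of_type("exon"):
        attrs = ex.attributes
        biotype = (attrs.get("gene_biotype") or attrs.get("gene_type") or ["unknown"])[0]
        rows.append((
            attrs["gene_id"][0], attrs["transcript_id"][0], ex.seqid,
            ex.start - 1, ex.end, ex.strand, biotype,
        ))
    return validate_exon_table(pd.DataFrame(rows, columns=EXON_COLUMNS))


def _merge_intervals(ivs) -> list:
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


@dataclass
class ChimericGeneModel:
    """Per-gene ordered disjoint merged-exon intervals.

    ``exons``: gene -> list of (start, end); ``chroms``/``strands``: gene ->
    chromosome / strand.  Only protein-coding transcripts contribute; genes
    without any protein-coding transcript are absent.
    """

    exons: dict
    chroms: dict
    strands: dict
    _trees: dict = field(default_factory=dict, repr=False)

    @property
    def genes(self) -> list:
        return list(self.exons)

    def chrom(self, gene: str) -> str:
        return self.chroms[gene]

    def exon_count(self, gene: str) -> int:
        return len(self.exons[gene])

    def exonic_length(self, gene: str) -> int:
        return sum(e - s for s, e in self.exons[gene])

    def lengths(self) -> pd.Series:
        return pd.Series({g: self.exonic_length(g) for g in self.exons}, name="length")

    def tree(self, chrom: str) -> IntervalTree:
        """Interval tree of exons on one chromosome: payload (gene, exon_idx)."""
        if chrom not in self._trees:
            t = IntervalTree()
            for gene, ivs in self.exons.items():
                if self.chroms[gene] != chrom:
                    continue
                for i, (s, e) in enumerate(ivs):
                    t.addi(s, e, (gene, i))
            self._trees[chrom] = t
        return self._trees[chrom]

    def to_exon_table(self) -> pd.DataFrame:
        rows = [
            (g, f"{g}.merged", self.chroms[g], s, e, self.strands[g], "protein_coding")
            for g, ivs in self.exons.items() for s, e in ivs
        ]
        return pd.DataFrame(rows, columns=EXON_COLUMNS)

    # -- helpers used by the synthetic alignment generator ------------------
    def exclusive_intervals(self) -> dict:
        """Per gene, exonic sub-intervals not covered by any other gene's exons."""
        out = {}
        for gene, ivs in self.exons.items():
            tree = self.tree(self.chroms[gene])
            kept = []
            for s, e in ivs:
                cuts = {s, e}
                others = [iv for iv in tree.overlap(s, e) if iv.data[0] != gene]
                for iv in others:
                    cuts.update(p for p in (iv.begin, iv.end) if s < p < e)
                pts = sorted(cuts)
                for a, b in zip(pts, pts[1:]):
                    mid = (a + b) // 2
                    if not any(o.begin <= mid < o.end for o in others):
                        kept.append((a, b))
            out[gene] = _merge_intervals(kept) if kept else []
        return out

    def overlapping_gene_pairs(self, max_gap: int = 50) -> list:
        """Regions a gene-ambiguous read can be built from.

        Returns (gene_a, gene_b, chrom, lo, hi, kind) records: ``shared``
        regions [lo, hi) are exonic in both genes (a read placed fully
        inside resolves to both genes at every base); ``bridge`` spans must
        be fully covered by a read so it touches exclusive exonic bases of
        both genes with only feature-free gap in between.
        """
        pairs = {}
        for gene, ivs in self.exons.items():
            tree = self.tree(self.chroms[gene])
            for s, e in ivs:
                for iv in tree.overlap(s - max_gap, e + max_gap):
                    other = iv.data[0]
                    if other <= gene:
                        continue
                    ov_lo = max(s, iv.begin)
                    ov_hi = min(e, iv.end)
                    if ov_lo < ov_hi:  # genuine exon overlap
                        region = (self.chroms[gene], ov_lo, ov_hi, "shared")
                    else:  # disjoint: span last base of one, first of other
                        region = (self.chroms[gene], ov_hi - 1, ov_lo + 1,
                                  "bridge")
                    key = (gene, other)
                    if key not in pairs or region[2] - region[1] < \
                            pairs[key][2] - pairs[key][1]:
                        pairs[key] = region
        return [(a, b, *r) for (a, b), r in sorted(pairs.items())]

    def intron_gaps(self, gene: str) -> list:
        ivs = self.exons[gene]
        return [(ivs[i][1], ivs[i + 1][0]) for i in range(len(ivs) - 1)]


def build_chimeric_model(exons: pd.DataFrame) -> ChimericGeneModel:
    """Merge all protein-coding transcripts of each gene into one model.

    Idempotent: rebuilding from ``model.to_exon_table()`` reproduces the
    model.  Genes with no protein-coding transcript are dropped.
    """
    validate_exon_table(exons)
    coding = exons[exons["biotype"] == "protein_coding"]
    merged, chroms, strands = {}, {}, {}
    for gene, grp in coding.groupby("gene_id", sort=True):
        if grp["chrom"].nunique() > 1:
            raise FormatError(f"gene {gene} spans multiple chromosomes")
        merged[gene] = _merge_intervals(list(zip(grp["start"], grp["end"])))
        chroms[gene] = grp["chrom"].iloc[0]
        strands[gene] = grp["strand"].iloc[0]
    return ChimericGeneModel(exons=merged, chroms=chroms, strands=strands)


def exon_coverage_filter(model: ChimericGeneModel,
                         alignments_by_sample: dict) -> tuple[list, list]:
    """Expression filter: drop a gene iff in EVERY sample reads hit < 50% of
    its merged exons.  Exactly 50% counts as expressed; one sample at or
    above 50% rescues the gene.
    """
    if not model.genes:
        raise ValueError("empty gene model")
    if not alignments_by_sample:
        raise ValueError("need at least one sample of alignments")

    best_frac = {g: 0.0 for g in model.genes}
    for sample, aln in alignments_by_sample.items():
        hit = set()
        for chrom, grp in aln.groupby("chrom"):
            tree = model.tree(chrom)
            for s, e in zip(grp["start"], grp["end"]):
                hit.update(iv.data for iv in tree.overlap(s, e))
        per_gene = {}
        for gene, _idx in hit:
            per_gene[gene] = per_gene.get(gene, 0) + 1
        for gene, n_hit in per_gene.items():
            frac = n_hit / model.exon_count(gene)
            if frac > best_frac[gene]:
                best_frac[gene] = frac
    kept = [g for g in model.genes if best_frac[g] >= 0.5]
    dropped = [g for g in model.genes if best_frac[g] < 0.5]
    return kept, dropped


def count_reads(model: ChimericGeneModel, alignments: pd.DataFrame,
                genes: list | None = None) -> pd.Series:
    """Count alignment intervals per gene, intersection-nonempty mode.

    Multi-mapped records (multiplicity > 1) are discarded; a record whose
    feature-covered bases resolve to exactly one gene increments that gene;
    records resolving to several genes or to no exonic base are discarded.
    Records on chromosomes absent from the model are skipped with a warning.
    """
    genes = list(genes) if genes is not None else model.genes
    gene_set = set(genes)
    counts = {g: 0 for g in genes}
    known_chroms = set(model.chroms.values())
    for rec in alignments.itertuples(index=False):
        if rec.multiplicity > 1:
            continue
        if rec.chrom not in known_chroms:
            log.warning("skipping read %s on unknown chromosome %s",
                        rec.read_id, rec.chrom)
            continue
        tree = model.tree(rec.chrom)
        hits = [iv for iv in tree.overlap(rec.start, rec.end)
                if iv.data[0] in gene_set]
        if not hits:
            continue
        # Elementary segments of the read covered by >=1 exon; intersect
        # their per-base gene sets (feature-free bases are ignored).
        cuts = {rec.start, rec.end}
        for iv in hits:
            cuts.update(p for p in (iv.begin, iv.end) if rec.start < p < rec.end)
        assigned = None
        for a, b in zip(*(lambda p: (p[:-1], p[1:]))(sorted(cuts))):
            here = {iv.data[0] for iv in hits if iv.begin < b and a < iv.end}
            if not here:
                continue
            assigned = here if assigned is None else (assigned & here)
        if assigned is not None and len(assigned) == 1:
            counts[assigned.pop()] += 1
    return pd.Series(counts, name="count").reindex(genes).astype(int)
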