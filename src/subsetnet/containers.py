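"""Shared in-memory containers for the pipeline."""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: Canonical sample order: two subsets (A, B) x two conditions.
SAMPLES = ("A_steady", "A_stim", "B_steady", "B_stim")
SUBSETS = ("A", "B")
CONDITIONS = ("steady", "stim")


@dataclass
class CountMatrix:
    """Genes x samples integer counts with gene lengths and sample labels.

    Column names encode the design as ``<subset>_<condition>``.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        self.counts.index.name = "gene_id"
        self.lengths = self.lengths.reindex(self.counts.index)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> list:
        return list(self.counts.columns)

    def sample_meta(self) -> pd.DataFrame:
        parts = [c.rsplit("_", 1) for c in self.counts.columns]
        return pd.DataFrame(parts, index=self.counts.columns,
                            columns=["subset", "condition"])

    def columns_for(self, subset: str) -> tuple:
        """(steady, stimulated) column names of one subset."""
        return (f"{subset}_steady", f"{subset}_stim")

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        lengths = df.pop("length")
        return cls(counts=df.astype(int), lengths=lengths.astype(float))


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset.

    ``genes`` is indexed by gene id with columns: length, mu (baseline NB
    mean), core (bool), de_A / de_B in {none, up, down}, modulator_of in
    {"", "A", "B"}.  ``terms`` records per-annotation-term planted odds and
    the enrichment flag.
    """

    genes: pd.DataFrame
    terms: pd.DataFrame = field(default_factory=pd.DataFrame)

    def de_set(self, subset: str) -> set:
        col = f"de_{subset}"
        return set(self.genes.index[self.genes[col] != "none"])

    def modulators(self, subset: str) -> set:
        return set(self.genes.index[self.genes["modulator_of"] == subset])

    @property
    def cores(self) -> list:
        return list(self.genes.index[self.genes["core"]])

    def to_tsv(self, path) -> None:
        self.genes.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class AnnotationSets:
    """Annotation term -> member gene set, with term metadata.

    ``meta`` is indexed by term with columns name and source
    (GO / Reactome / TF-target).
    """

    terms: dict
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.terms = {t: frozenset(m) for t, m in self.terms.items() if m}
        self.meta = self.meta.loc[[t for t in self.meta.index if t in self.terms]]

    def restrict(self, universe: set) -> "AnnotationSets":
        """Intersect members with a gene universe; drop emptied terms."""
        uni = set(universe)
        kept = {t: m & uni for t, m in self.terms.items() if m & uni}
        return AnnotationSets(terms=kept, meta=self.meta.loc[list(kept)])

    def __len__(self) -> int:
        return len(self.terms)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for term in self.meta.index:
                desc = self.meta.loc[term, "name"]
                members = "\t".join(sorted(self.terms[term]))
                fh.write(f"{term}\t{desc}\t{members}\n")

    @classmethod
    def from_gmt(cls, path) -> "AnnotationSets":
        terms, names = {}, []
        text = Path(path).read_text() if not isinstance(path, io.IOBase) else path.read()
        for line in text.splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line needs >=3 fields: {line[:60]!r}")
            terms[parts[0]] = frozenset(parts[2:])
            names.append((parts[0], parts[1]))
        meta = pd.DataFrame(names, columns=["term", "name"]).set_index("term")
        meta["source"] = "GO"
        return cls(terms=terms, meta=meta)
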