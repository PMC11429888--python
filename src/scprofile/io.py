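"""Readers and writers for the standard genomics formats the package uses.

FASTA (genome), GTF (genes/exons; 1-based inclusive coordinates per the GTF
convention), BED (peaks and region splits; 0-based half-open), and TSVs for
cell metadata and embeddings. Reading FASTA goes through pyfaidx.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Gene:
    """Gene with exons; 0-based half-open genomic coordinates in memory."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple = ()  # ((start, end), ...) sorted, 0-based half-open

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GeneSet:
    genes: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.genes)

    def __len__(self):
        return len(self.genes)

    def __getitem__(self, name: str) -> Gene:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(f"gene {name!r} not in annotation")

    @property
    def names(self) -> list:
        return [g.name for g in self.genes]


def write_fasta(sequences: dict, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict:
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_gtf(genes: GeneSet, path, source: str = "scprofile") -> None:
    """GTF: 1-based inclusive coordinates; gene + transcript + exon rows."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.name}"; transcript_id "{g.name}.t1";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\t{source}\ttranscript\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


def read_gtf(path) -> GeneSet:
    """Minimal GTF reader for gene/exon features (converts to 0-based)."""
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, feature, start, end, strand, attrs = (
                f[0], f[2], int(f[3]) - 1, int(f[4]), f[6], f[8]
            )
            gene_id = attrs.split('gene_id "')[1].split('"')[0]
            rec = genes.setdefault(
                gene_id,
                {"chrom": chrom, "strand": strand, "start": None, "end": None,
                 "exons": []},
            )
            if feature == "gene":
                rec["start"], rec["end"] = start, end
            elif feature == "exon":
                rec["exons"].append((start, end))
    out = []
    for name, rec in genes.items():
        exons = tuple(sorted(rec["exons"]))
        start = rec["start"] if rec["start"] is not None else exons[0][0]
        end = rec["end"] if rec["end"] is not None else exons[-1][1]
        out.append(Gene(name, rec["chrom"], start, end, rec["strand"], exons))
    return GeneSet(out)


def write_bed(intervals, path) -> None:
    """intervals: iterable of (chrom, start, end[, name[, extra...]])."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2]), *f[3:]))
    return out


def write_fragments_tsv(store, path) -> None:
    """Fragment TSV: chrom, start, end, barcode, count, strand."""
    with open(path, "w") as fh:
        for r in store.records():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.barcode}\t"
                     f"{r.count}\t{r.strand}\n")


def write_embeddings_tsv(barcodes, embeddings, path) -> None:
    df = pd.DataFrame(np.asarray(embeddings), index=list(barcodes))
    df.columns = [f"e{i}" for i in range(df.shape[1])]
    df.to_csv(path, sep="\t", index_label="barcode")


def read_embeddings_tsv(path):
    df = pd.read_csv(path, sep="\t", index_col="barcode")
    return list(df.index), df.values


def write_cell_metadata(barcodes, labels, depth_factors, path) -> None:
    pd.DataFrame(
        {"barcode": list(barcodes),
         "cell_type": [labels[b] for b in barcodes],
         "depth_factor": list(depth_factors)}
    ).to_csv(path, sep="\t", index=False)


def read_cell_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="barcode")
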