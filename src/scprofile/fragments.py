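"""Per-cell genomic fragment storage and on-the-fly coverage binning.

Fragments are the substrate both assays share: scATAC fragment files are
already fragment records, and scRNA aligned reads are decomposed into one
record per contiguous exonic block (split reads become multiple entries).
Records carry only start + length per cell, the compact encoding that makes
on-the-fly coverage extraction cheap.

Coverage semantics per assay:

* RNA — base-pair-overlap-weighted coverage per strand; a fragment
  contributes its overlapping bases to each 32-bp bin, on its strand's track.
* ATAC — Tn5 insertion counts; each fragment [s, s+len) contributes two
  insertion events, at ``s`` and ``s + len - 1`` (both ends lie on covered
  bases).

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import h5py
import numpy as np


BIN_WIDTH = 32
_STRAND_CODE = {"+": 0, "-": 1, ".": 0}
_STRAND_CHAR = {0: "+", 1: "-"}


@dataclass(frozen=True)
class FragmentRecord:
    """One fragment: half-open span [start, start+length) of one cell."""

    chrom: str
    start: int
    length: int
    barcode: str
    count: int = 1
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.length < 1:
            raise ValueError(f"non-positive length {self.length}")

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class BinnedProfile:
    """Per-cell signal over fixed-width bins.

    values: (cells, bins, tracks); RNA has 2 strand tracks (+, -), ATAC 1.
    """

    values: np.ndarray
    chrom: str
    start: int
    bin_width: int = BIN_WIDTH
    scale: str = "natural"
    barcodes: list = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def end(self) -> int:
        return self.start + self.bin_width * self.n_bins


class FragmentStore:
    """Columnar per-chromosome fragment collections with a barcode index.

    Within each chromosome, records are kept sorted by (cell, start) so that
    one cell's records form a contiguous, position-sorted slice.
    """

    def __init__(self, assay: str, barcodes, chrom_sizes: dict | None = None,
                 insertions: bool = False):
        if assay not in ("rna", "atac"):
            raise ValueError(f"assay must be 'rna' or 'atac', got {assay!r}")
        if insertions and assay != "atac":
            raise ValueError("insertion stores are ATAC-only")
        self.assay = assay
        self.barcodes = list(barcodes)
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes")
        self.barcode_index = {b: i for i, b in enumerate(self.barcodes)}
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes else None
        self.insertions = insertions
        # chrom -> dict of parallel arrays: start, length, cell, strand, count
        self._data: dict[str, dict[str, np.ndarray]] = {}

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(cls, records, assay: str, barcodes=None,
                     chrom_sizes: dict | None = None,
                     insertions: bool = False) -> "FragmentStore":
        records = list(records)
        if barcodes is None:
            barcodes = sorted({r.barcode for r in records})
        store = cls(assay, barcodes, chrom_sizes, insertions)
        by_chrom: dict[str, list] = {}
        for r in records:
            if r.barcode not in store.barcode_index:
                raise KeyError(f"barcode {r.barcode!r} not in store index")
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, recs in by_chrom.items():
            store._data[chrom] = store._columnize(recs)
        return store

    def _columnize(self, recs) -> dict[str, np.ndarray]:
        cell = np.array([self.barcode_index[r.barcode] for r in recs], dtype=np.int64)
        start = np.array([r.start for r in recs], dtype=np.int64)
        length = np.array([r.length for r in recs], dtype=np.int64)
        strand = np.array([_STRAND_CODE[r.strand] for r in recs], dtype=np.int8)
        count = np.array([r.count for r in recs], dtype=np.int64)
        order = np.lexsort((start, cell))
        return {"cell": cell[order], "start": start[order],
                "length": length[order], "strand": strand[order],
                "count": count[order]}

    # -- access ------------------------------------------------------------
    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    @property
    def n_records(self) -> int:
        return sum(len(d["start"]) for d in self._data.values())

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def records(self):
        """Iterate records (sorted by chrom, then cell, then start)."""
        for chrom in self.chroms:
            d = self._data[chrom]
            for i in range(len(d["start"])):
                yield FragmentRecord(
                    chrom, int(d["start"][i]), int(d["length"][i]),
                    self.barcodes[int(d["cell"][i])], int(d["count"][i]),
                    _STRAND_CHAR[int(d["strand"][i])],
                )

    def _chrom_arrays(self, chrom: str):
        return self._data.get(chrom)

    # -- serialization (lossless) -------------------------------------------
    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["assay"] = self.assay
            f.attrs["insertions"] = self.insertions
            f.create_dataset(
                "barcodes", data=np.array(self.barcodes, dtype=h5py.string_dtype())
            )
            if self.chrom_sizes:
                grp = f.create_group("chrom_sizes")
                for c, s in self.chrom_sizes.items():
                    grp.attrs[c] = s
            frags = f.create_group("fragments")
            for chrom, d in self._data.items():
                g = frags.create_group(chrom)
                for key, arr in d.items():
                    g.create_dataset(key, data=arr)

    @classmethod
    def load(cls, path: str) -> "FragmentStore":
        with h5py.File(path, "r") as f:
            barcodes = [b.decode() for b in f["barcodes"][...]]
            sizes = None
            if "chrom_sizes" in f:
                sizes = {c: int(v) for c, v in f["chrom_sizes"].attrs.items()}
            store = cls(str(f.attrs["assay"]), barcodes, sizes,
                        bool(f.attrs["insertions"]))
            for chrom in f["fragments"]:
                g = f["fragments"][chrom]
                store._data[chrom] = {k: g[k][...] for k in g}
        return store


# -- parsing ----------------------------------------------------------------

def _open_text(path):
    p = str(path)
    return gzip.open(p, "rt") if p.endswith(".gz") else open(p)


def parse_fragment_file(path, assay: str, whitelist=None,
                        deduplicate: bool = False,
                        chrom_sizes: dict | None = None) -> FragmentStore:
    """Read a fragment TSV (chrom, start, end, barcode[, count][, strand]).

    Coordinates are 0-based half-open. Records whose barcode is outside the
    whitelist are dropped; with ``deduplicate`` exact duplicates (same chrom,
    start, end, barcode) collapse to a single record. Records with
    ``end <= start`` are rejected with their line number, as are chromosomes
    absent from ``chrom_sizes`` when sizes are provided.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"line {lineno}: expected >= 4 columns")
            chrom, start, end, barcode = parts[0], int(parts[1]), int(parts[2]), parts[3]
            count, strand = 1, "."
            for extra in parts[4:6]:
                if extra in ("+", "-", "."):
                    strand = extra
                else:
                    count = int(extra)
            if end <= start:
                raise ValueError(f"line {lineno}: end {end} <= start {start}")
            if chrom_sizes is not None and chrom not in chrom_sizes:
                raise ValueError(f"line {lineno}: unknown chromosome {chrom!r}")
            rows.append((chrom, start, end, barcode, count, strand))
    if whitelist is not None:
        whitelist = set(whitelist)
        rows = [r for r in rows if r[3] in whitelist]
        barcodes = sorted(whitelist)
    else:
        barcodes = sorted({r[3] for r in rows})
    if deduplicate:
        seen = {}
        for r in rows:
            seen.setdefault((r[0], r[1], r[2], r[3], r[5]), r)
        rows = list(seen.values())
    records = [
        FragmentRecord(c, s, e - s, b, n, st) for c, s, e, b, n, st in rows
    ]
    return FragmentStore.from_records(records, assay, barcodes, chrom_sizes)


def reads_to_fragments(path, whitelist=None, deduplicate: bool = True,
                       xf_filter: bool = True,
                       chrom_sizes: dict | None = None) -> FragmentStore:
    """Convert a simplified aligned-read TSV into an RNA fragment store.

    Columns: chrom, blocks ("s1-e1,s2-e2", 0-based half-open exonic blocks),
    strand, barcode, umi, xf. With ``xf_filter`` only reads whose xf flag is
    25 (marked valid by the upstream pipeline) are kept. Each read yields one
    record per block (split reads become multiple entries); duplicates are
    collapsed on (chrom, blocks, barcode, umi).
    """
    reads = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, blocks, strand, barcode, umi, xf = line.split("\t")[:6]
            if xf_filter and int(xf) != 25:
                continue
            if whitelist is not None and barcode not in whitelist:
                continue
            reads.append((chrom, blocks, strand, barcode, umi))
    if deduplicate:
        reads = list(dict.fromkeys(reads))
    records = []
    for chrom, blocks, strand, barcode, _umi in reads:
        for blk in blocks.split(","):
            s, e = map(int, blk.split("-"))
            if e <= s:
                raise ValueError(f"empty block {blk!r}")
            records.append(FragmentRecord(chrom, s, e - s, barcode, 1, strand))
    barcodes = sorted(whitelist) if whitelist is not None else None
    return FragmentStore.from_records(records, "rna", barcodes, chrom_sizes)


# -- insertions --------------------------------------------------------------

def fragments_to_insertions(store: FragmentStore) -> FragmentStore:
    """Convert an ATAC fragment store to Tn5 insertion events.

    Each fragment [s, s+len) yields two length-1 records at ``s`` and
    ``s+len-1`` (the cut sites, kept on covered bases), so the output holds
    exactly twice as many records.
    """
    if store.assay != "atac":
        raise ValueError("insertion conversion applies to ATAC stores only")
    if store.insertions:
        raise ValueError("store already holds insertion events")
    out = FragmentStore("atac", store.barcodes, store.chrom_sizes, insertions=True)
    for chrom, d in store._data.items():
        left = d["start"]
        right = d["start"] + d["length"] - 1
        starts = np.concatenate([left, right])
        cells = np.concatenate([d["cell"], d["cell"]])
        counts = np.concatenate([d["count"], d["count"]])
        order = np.lexsort((starts, cells))
        out._data[chrom] = {
            "cell": cells[order],
            "start": starts[order],
            "length": np.ones(len(starts), dtype=np.int64),
            "strand": np.zeros(len(starts), dtype=np.int8),
            "count": counts[order],
        }
    return out


# -- binning -----------------------------------------------------------------

def _cell_slice(d: dict, cell_idx: int):
    lo = np.searchsorted(d["cell"], cell_idx, side="left")
    hi = np.searchsorted(d["cell"], cell_idx, side="right")
    return slice(lo, hi)


def bin_coverage(store: FragmentStore, chrom: str, start: int, n_bins: int,
                 cells=None, bin_width: int = BIN_WIDTH,
                 clip: bool = False) -> BinnedProfile:
    """Natural-scale binned signal over [start, start + bin_width*n_bins).

    RNA: per-strand base-pair overlap; ATAC: insertion counts (fragment ends
    are converted on the fly unless the store already holds insertions).
    Regions beyond the chromosome end raise unless ``clip`` is set, in which
    case out-of-genome positions simply contribute nothing (used for windows
    centered near chromosome edges).
    """
    if cells is None:
        cells = store.barcodes
    width = bin_width * n_bins
    end = start + width
    if store.chrom_sizes is not None:
        if chrom not in store.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not clip and (start < 0 or end > store.chrom_sizes[chrom]):
            raise ValueError(
                f"region [{start}, {end}) outside {chrom} "
                f"(length {store.chrom_sizes[chrom]})"
            )
    n_tracks = 2 if store.assay == "rna" else 1
    cell_idx = [store.barcode_index[b] for b in cells]
    values = np.zeros((len(cells), n_bins, n_tracks), dtype=np.float64)
    d = store._chrom_arrays(chrom)
    if d is None:
        return BinnedProfile(values, chrom, start, bin_width,
                             barcodes=list(cells))
    for row, ci in enumerate(cell_idx):
        sl = _cell_slice(d, ci)
        starts = d["start"][sl]
        lengths = d["length"][sl]
        strands = d["strand"][sl]
        counts = d["count"][sl]
        if store.assay == "rna":
            for tr in (0, 1):
                m = strands == tr
                if not m.any():
                    continue
                lo = np.clip(starts[m] - start, 0, width)
                hi = np.clip(starts[m] + lengths[m] - start, 0, width)
                keep = hi > lo
                if not keep.any():
                    continue
                diff = np.zeros(width + 1)
                np.add.at(diff, lo[keep], counts[m][keep].astype(float))
                np.add.at(diff, hi[keep], -counts[m][keep].astype(float))
                per_base = np.cumsum(diff[:-1])
                values[row, :, tr] = per_base.reshape(n_bins, bin_width).sum(axis=1)
        else:
            if store.insertions:
                pos = starts
                w = counts.astype(float)
            else:
                pos = np.concatenate([starts, starts + lengths - 1])
                w = np.concatenate([counts, counts]).astype(float)
            inside = (pos >= start) & (pos < end)
            b = (pos[inside] - start) // bin_width
            np.add.at(values[row, :, 0], b, w[inside])
    return BinnedProfile(values, chrom, start, bin_width, barcodes=list(cells))


def export_bigwig(store: FragmentStore, labels: dict, outdir,
                  bin_width: int = BIN_WIDTH) -> list:
    """Export per-cell-type pseudobulk binned coverage to bigWig files.

    ``labels`` maps barcode -> cell type. Requires chrom_sizes on the store.
    Returns the written paths.
    """
    import os

    import pyBigWig

    if store.chrom_sizes is None:
        raise ValueError("bigWig export requires chromosome sizes")
    paths = []
    cell_types = sorted(set(labels.values()))
    for ct in cell_types:
        members = [b for b in store.barcodes if labels.get(b) == ct]
        path = os.path.join(str(outdir), f"{ct}.bw")
        bw = pyBigWig.open(path, "w")
        header = [(c, store.chrom_sizes[c]) for c in sorted(store.chrom_sizes)]
        bw.addHeader(header)
        for chrom, size in header:
            n_bins = size // bin_width
            prof = bin_coverage(store, chrom, 0, n_bins, cells=members,
                                bin_width=bin_width)
            vals = prof.values.sum(axis=(0, 2)).astype(np.float64)
            starts = np.arange(n_bins, dtype=np.int64) * bin_width
            bw.addEntries(chrom, starts.tolist(),
                          values=vals.tolist(), span=bin_width)
        bw.close()
        paths.append(path)
    return paths
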