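"""Shared in-memory containers and their plain-text I/O.

Five containers flow between the analysis stages:

* :class:`SiteAlleleCounts` -- per-individual read counts for the two observed
  alleles at biallelic sites (TSV-backed).
* :class:`BaseFrequencySet` -- denoised per-site allele frequencies in (0, 1),
  stored in the unfolded, mirrored representation (every site contributes both
  ``f`` and ``1 - f``).
* :class:`LocusAlignment` -- phased haplotype sequences for one locus with
  individual/species/ploidy labels (FASTA-backed).
* :class:`TreeSet` -- leaf-labelled topologies on a shared taxon namespace
  (newick-list-backed).
* :class:`SuitabilityRaster` -- gridded presence probabilities with simple
  georeferencing metadata (ESRI ASCII grid backed).
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COUNTS_COLUMNS = [
    "individual",
    "species",
    "locus",
    "site",
    "countA",
    "countB",
    "countOther",
]

# --------------------------------------------------------------------------- #
# allele counts
# --------------------------------------------------------------------------- #


@dataclass
class SiteAlleleCounts:
    """Read counts for the two observed alleles at each site of one individual.

    ``allele_a``/``allele_b`` optionally carry the base identities of the two
    alleles per site; when absent, allele labels are assumed consistent across
    individuals (the convention of the synthetic generators, where A is the
    reference allele everywhere).
    """

    individual_id: str
    species_label: str
    locus_ids: np.ndarray
    site_index: np.ndarray
    count_a: np.ndarray
    count_b: np.ndarray
    count_other: np.ndarray
    allele_a: np.ndarray | None = None
    allele_b: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.locus_ids = np.asarray(self.locus_ids)
        self.site_index = np.asarray(self.site_index, dtype=np.int64)
        self.count_a = np.asarray(self.count_a, dtype=np.int64)
        self.count_b = np.asarray(self.count_b, dtype=np.int64)
        self.count_other = np.asarray(self.count_other, dtype=np.int64)
        n = len(self.site_index)
        for arr in (self.locus_ids, self.count_a, self.count_b, self.count_other):
            if len(arr) != n:
                raise ValueError("count arrays must share one length")
        if (self.count_a < 0).any() or (self.count_b < 0).any() or (
            self.count_other < 0
        ).any():
            raise ValueError("read counts must be non-negative")

    def __len__(self) -> int:
        return len(self.site_index)

    @property
    def depth(self) -> np.ndarray:
        return self.count_a + self.count_b + self.count_other

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual": self.individual_id,
                "species": self.species_label,
                "locus": self.locus_ids,
                "site": self.site_index,
                "countA": self.count_a,
                "countB": self.count_b,
                "countOther": self.count_other,
            }
        )


def write_counts_tsv(counts: list[SiteAlleleCounts], path: str) -> None:
    """Write allele counts as the canonical tab-separated table."""
    frame = pd.concat([c.to_frame() for c in counts], ignore_index=True)
    frame.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str) -> list[SiteAlleleCounts]:
    """Read a counts TSV (header required, 0-based sites) into per-individual sets."""
    frame = pd.read_csv(path, sep="\t")
    missing = set(COUNTS_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    out = []
    for ind, sub in frame.groupby("individual", sort=False):
        species = str(sub["species"].iloc[0])
        out.append(
            SiteAlleleCounts(
                individual_id=str(ind),
                species_label=species,
                locus_ids=sub["locus"].to_numpy(),
                site_index=sub["site"].to_numpy(),
                count_a=sub["countA"].to_numpy(),
                count_b=sub["countB"].to_numpy(),
                count_other=sub["countOther"].to_numpy(),
            )
        )
    return out


# --------------------------------------------------------------------------- #
# base frequencies
# --------------------------------------------------------------------------- #


@dataclass
class BaseFrequencySet:
    """Unfolded biallelic base frequencies for one individual.

    Entries come in mirrored pairs: a site with alternate-allele frequency
    ``f`` contributes both ``f`` and ``1 - f``, so the multiset is symmetric
    about 0.5 (the convention of nQuire-style frequency histograms).
    """

    individual_id: str
    freqs: np.ndarray
    depths: np.ndarray
    signal_posterior: np.ndarray | None = None
    warning: str | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.signal_posterior is None:
            self.signal_posterior = np.ones_like(self.freqs)
        else:
            self.signal_posterior = np.asarray(self.signal_posterior, dtype=float)
        if len(self.freqs) % 2:
            raise ValueError("mirrored representation requires an even entry count")
        if len(self.freqs) and (
            (self.freqs <= 0).any() or (self.freqs >= 1).any()
        ):
            raise ValueError("frequencies must lie strictly inside (0, 1)")

    def __len__(self) -> int:
        return len(self.freqs)

    @property
    def n_sites(self) -> int:
        return len(self.freqs) // 2

    @classmethod
    def from_site_frequencies(
        cls, individual_id: str, f: np.ndarray, depth: np.ndarray
    ) -> "BaseFrequencySet":
        """Build the mirrored set from one frequency per site."""
        f = np.asarray(f, dtype=float)
        depth = np.asarray(depth, dtype=np.int64)
        return cls(
            individual_id=individual_id,
            freqs=np.concatenate([f, 1.0 - f]),
            depths=np.concatenate([depth, depth]),
        )

    def subset(self, mask: np.ndarray) -> "BaseFrequencySet":
        out = replace(
            self,
            freqs=self.freqs[mask],
            depths=self.depths[mask],
            signal_posterior=self.signal_posterior[mask],
        )
        return out


# --------------------------------------------------------------------------- #
# locus alignments
# --------------------------------------------------------------------------- #

_FASTA_HEADER = re.compile(r"^(?P<ind>[^|]+)\|h(?P<hap>\d+)\|(?P<sp>[^|]+)\|(?P<pl>\d+)$")


@dataclass
class LocusAlignment:
    """Phased haplotype alignment for a single locus.

    ``matrix`` is an ``(n_rows, n_sites)`` byte array over ``A C G T - N``;
    each row is one haplotype labelled with its individual, haplotype index,
    species and ploidy.
    """

    locus_id: str
    individual_ids: list[str]
    haplotype_index: list[int]
    species_labels: list[str]
    ploidies: list[int]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="S1")
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        n = self.matrix.shape[0]
        if not (
            len(self.individual_ids)
            == len(self.haplotype_index)
            == len(self.species_labels)
            == len(self.ploidies)
            == n
        ):
            raise ValueError("row labels must match matrix row count")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def sequences(self) -> list[str]:
        return [row.tobytes().decode() for row in self.matrix]

    def rows_for_species(self, species: str) -> np.ndarray:
        return np.array([s == species for s in self.species_labels])

    def take_rows(self, idx) -> "LocusAlignment":
        idx = np.asarray(idx)
        return LocusAlignment(
            locus_id=self.locus_id,
            individual_ids=[self.individual_ids[i] for i in idx],
            haplotype_index=[self.haplotype_index[i] for i in idx],
            species_labels=[self.species_labels[i] for i in idx],
            ploidies=[self.ploidies[i] for i in idx],
            matrix=self.matrix[idx],
        )


def write_fasta_locus(aln: LocusAlignment, path: str) -> None:
    """Write one locus using the ``>INDIVIDUAL|hN|SPECIES|PLOIDY`` header convention."""
    records = []
    for i, seq in enumerate(aln.sequences()):
        name = (
            f"{aln.individual_ids[i]}|h{aln.haplotype_index[i]}|"
            f"{aln.species_labels[i]}|{aln.ploidies[i]}"
        )
        records.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(records, path, "fasta")


def read_fasta_locus(path: str, locus_id: str | None = None) -> LocusAlignment:
    inds, haps, sps, pls, seqs = [], [], [], [], []
    for rec in SeqIO.parse(path, "fasta"):
        m = _FASTA_HEADER.match(rec.id)
        if not m:
            raise ValueError(
                f"{path}: header {rec.id!r} does not follow INDIVIDUAL|hN|SPECIES|PLOIDY"
            )
        inds.append(m["ind"])
        haps.append(int(m["hap"]))
        sps.append(m["sp"])
        pls.append(int(m["pl"]))
        seqs.append(str(rec.seq).upper())
    if not seqs:
        raise ValueError(f"{path}: empty alignment")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"{path}: unequal sequence lengths {sorted(lengths)}")
    matrix = np.array([np.frombuffer(s.encode(), dtype="S1") for s in seqs])
    if locus_id is None:
        locus_id = os.path.splitext(os.path.basename(path))[0]
    return LocusAlignment(locus_id, inds, haps, sps, pls, matrix)


def read_fasta_loci(directory: str) -> list[LocusAlignment]:
    """Read every ``*.fa``/``*.fasta`` file in a directory, sorted by name."""
    paths = sorted(
        os.path.join(directory, p)
        for p in os.listdir(directory)
        if p.endswith((".fa", ".fasta"))
    )
    return [read_fasta_locus(p) for p in paths]


# --------------------------------------------------------------------------- #
# tree sets
# --------------------------------------------------------------------------- #


@dataclass
class TreeSet:
    """A list of leaf-labelled topologies sharing one taxon namespace."""

    trees: dendropy.TreeList
    locus_ids: list[str] = field(default_factory=list)
    truth: np.ndarray | None = None  # generator labels, for recovery tests

    def __post_init__(self) -> None:
        if not self.locus_ids:
            self.locus_ids = [f"L{i}" for i in range(len(self.trees))]
        if len(self.locus_ids) != len(self.trees):
            raise ValueError("locus_ids must match tree count")

    def __len__(self) -> int:
        return len(self.trees)

    @property
    def taxon_namespace(self) -> dendropy.TaxonNamespace:
        return self.trees.taxon_namespace


def read_newick_list(path: str) -> TreeSet:
    """Read a one-tree-per-line newick file; ``#locus_id`` comments name loci."""
    tns = dendropy.TaxonNamespace()
    trees = dendropy.TreeList(taxon_namespace=tns)
    locus_ids: list[str] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            locus = f"L{i}"
            if "#" in line:
                line, _, comment = line.partition("#")
                line = line.strip()
                if comment.strip():
                    locus = comment.strip()
                if not line:
                    continue
            tree = dendropy.Tree.get(
                data=line, schema="newick", taxon_namespace=tns
            )
            trees.append(tree)
            locus_ids.append(locus)
    return TreeSet(trees=trees, locus_ids=locus_ids)


def write_newick_list(ts: TreeSet, path: str) -> None:
    with open(path, "w") as fh:
        for locus, tree in zip(ts.locus_ids, ts.trees):
            nwk = tree.as_string(schema="newick", suppress_rooting=True).strip()
            fh.write(f"{nwk} #{locus}\n")


# --------------------------------------------------------------------------- #
# suitability rasters
# --------------------------------------------------------------------------- #


@dataclass
class SuitabilityRaster:
    """Gridded presence probabilities in [0, 1] with a nodata mask."""

    data: np.ndarray
    nodata_mask: np.ndarray | None = None
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 1.0
    crs: str = "EPSG:4326"
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.data.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.data.shape:
                raise ValueError("nodata mask shape mismatch")
        valid = self.data[~self.nodata_mask]
        if valid.size and ((valid < 0).any() or (valid > 1).any()):
            raise ValueError("presence probabilities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def write_esri_ascii(raster: SuitabilityRaster, path: str) -> None:
    nrow, ncol = raster.shape
    grid = raster.data.copy()
    grid[raster.nodata_mask] = raster.nodata_value
    with open(path, "w") as fh:
        fh.write(f"ncols {ncol}\n")
        fh.write(f"nrows {nrow}\n")
        fh.write(f"xllcorner {raster.xllcorner}\n")
        fh.write(f"yllcorner {raster.yllcorner}\n")
        fh.write(f"cellsize {raster.cellsize}\n")
        fh.write(f"NODATA_value {raster.nodata_value}\n")
        for row in grid:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_esri_ascii(path: str, crs: str = "EPSG:4326") -> SuitabilityRaster:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "cellsize",
                "nodata_value",
            }:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    data = np.array(rows, dtype=float)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: grid shape does not match header")
    nodata = header.get("nodata_value", -9999.0)
    mask = data == nodata
    data = np.where(mask, 0.0, data)
    return SuitabilityRaster(
        data=data,
        nodata_mask=mask,
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        cellsize=header.get("cellsize", 1.0),
        crs=crs,
        nodata_value=nodata,
    )
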