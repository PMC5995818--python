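"""Genotype matrices, marker maps and standard-format I/O.

The central container is :class:`GenotypeMatrix`: an individuals x markers
table of allele-A dosages in ``{0, 1, 2}`` with ``-1`` for missing, together
with sample identifiers and a marker map (chromosome, identifier, 1-based
base-pair position).  Allele A is the first allele encountered in a .ped
file, or REF in a VCF; all LD magnitudes downstream (|D'|, r2) are invariant
to this orientation.  Missing genotypes are never imputed.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeFormatError",
    "GenotypeMatrix",
    "make_marker_map",
    "validate_marker_map",
    "read_ped_map",
    "write_ped_map",
    "read_vcf",
    "write_vcf",
    "allele_stats",
    "write_tables",
]

log = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype.
MISSING = -1

MAP_COLUMNS = ("chrom", "id", "pos")


class GenotypeFormatError(ValueError):
    """Raised when an input file violates the expected genotype format."""


def _chrom_sort_key(label: str):
    """Numeric chromosome labels sort numerically, others lexically after."""
    try:
        return (0, int(label), "")
    except ValueError:
        return (1, 0, label)


def make_marker_map(chrom, ids, pos, a1=None, a2=None) -> pd.DataFrame:
    """Assemble a marker map DataFrame (columns chrom, id, pos [, a1, a2])."""
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chrom, dtype=str),
            "id": pd.Series(ids, dtype=str),
            "pos": pd.Series(pos, dtype=np.int64),
        }
    )
    if a1 is not None:
        df["a1"] = pd.Series(a1, dtype=str)
        df["a2"] = pd.Series(a2, dtype=str)
    validate_marker_map(df)
    return df


def validate_marker_map(markers: pd.DataFrame) -> None:
    """Check marker-map invariants.

    Positions must be positive and strictly increasing within each
    chromosome; marker identifiers must be unique.
    """
    for col in MAP_COLUMNS:
        if col not in markers.columns:
            raise GenotypeFormatError(f"marker map lacks required column {col!r}")
    if markers["id"].duplicated().any():
        dup = markers.loc[markers["id"].duplicated(), "id"].iloc[0]
        raise GenotypeFormatError(f"duplicate marker identifier {dup!r}")
    if (markers["pos"] <= 0).any():
        raise GenotypeFormatError("marker positions must be positive (1-based)")
    for chrom, grp in markers.groupby("chrom", sort=False):
        p = grp["pos"].to_numpy()
        if np.any(np.diff(p) <= 0):
            raise GenotypeFormatError(
                f"positions not strictly increasing on chromosome {chrom}"
            )


@dataclasses.dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes as allele-A dosages.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_markers)`` int8 array with values in
        ``{0, 1, 2, MISSING}``.
    samples
        Individual identifiers, one per row.
    markers
        Marker map DataFrame with columns ``chrom``, ``id``, ``pos`` and
        optionally allele labels ``a1`` (allele A) and ``a2``.
    """

    dosages: np.ndarray
    samples: list
    markers: pd.DataFrame

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise GenotypeFormatError("dosage array must be 2-dimensional")
        if len(self.samples) != self.dosages.shape[0]:
            raise GenotypeFormatError("sample count does not match dosage rows")
        if len(self.markers) != self.dosages.shape[1]:
            raise GenotypeFormatError("marker map length does not match dosage columns")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeFormatError("dosages must be in {0, 1, 2, missing}")
        validate_marker_map(self.markers)
        self.samples = list(self.samples)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given row/column indices."""
        si = np.arange(self.n_individuals) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            self.dosages[np.ix_(si, mi)],
            [self.samples[i] for i in si],
            self.markers.iloc[mi].reset_index(drop=True),
        )

    def chromosomes(self):
        """Chromosome labels in map order (first appearance)."""
        return list(dict.fromkeys(self.markers["chrom"]))


# ---------------------------------------------------------------------------
# PLINK text .ped/.map
# ---------------------------------------------------------------------------

def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK text .ped/.map files into a :class:`GenotypeMatrix`.

    Allele A at each marker is the first non-missing allele encountered
    scanning individuals in file order; a ``0`` allele codes missing (PLINK
    convention), and a genotype with either allele missing is missing.
    Markers are sorted by (chromosome, position).

    The .ped format does not record which allele a dosage counts, so a
    write/read cycle reproduces the labeled genotypes exactly but may flip
    the dosage orientation (d -> 2 - d with a1/a2 swapped) at markers whose
    first-scanned individual is homozygous for allele 2; every reported
    statistic (MAF, call rate, |D'|, r^2, F, G) is invariant to this.
    """
    map_rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 4:
                chrom, mid, _cm, bp = parts
            elif len(parts) == 3:
                chrom, mid, bp = parts
            else:
                raise GenotypeFormatError(f"{map_path}:{ln}: expected 3 or 4 columns")
            map_rows.append((chrom, mid, int(bp)))
    m = len(map_rows)

    rows, samples = [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise GenotypeFormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} fields "
                    f"({m} markers), found {len(parts)}"
                )
            samples.append(parts[1])
            rows.append(parts[6:])
    n = len(rows)
    alleles = np.array(rows, dtype="U8").reshape(n, m, 2) if n else np.empty((0, m, 2), "U8")

    dosages = np.full((n, m), MISSING, dtype=np.int8)
    a1 = np.empty(m, dtype="U8")
    a2 = np.empty(m, dtype="U8")
    for j in range(m):
        col = alleles[:, j, :]
        observed = [a for a in dict.fromkeys(col.ravel()) if a != "0"]
        if len(observed) > 2:
            raise GenotypeFormatError(
                f"marker {map_rows[j][1]!r} has more than two alleles: {observed}"
            )
        first = observed[0] if observed else "A"
        second = observed[1] if len(observed) > 1 else ("B" if first != "B" else "A")
        a1[j], a2[j] = first, second
        if n:
            miss = (col == "0").any(axis=1)
            dosages[:, j] = np.where(miss, MISSING, (col == first).sum(axis=1))

    # sort per the map invariant, then validate via the constructor
    order = sorted(
        range(m), key=lambda j: (_chrom_sort_key(map_rows[j][0]), map_rows[j][2])
    )
    markers = pd.DataFrame(
        {
            "chrom": pd.Series([map_rows[j][0] for j in order], dtype=str),
            "id": pd.Series([map_rows[j][1] for j in order], dtype=str),
            "pos": pd.Series([map_rows[j][2] for j in order], dtype=np.int64),
            "a1": pd.Series(a1[order], dtype=str) if m else pd.Series(dtype=str),
            "a2": pd.Series(a2[order], dtype=str) if m else pd.Series(dtype=str),
        }
    )
    dosages = dosages[:, order]
    return GenotypeMatrix(dosages, samples, markers)


def write_ped_map(genotypes: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PLINK text .ped/.map files (deterministic, byte-stable)."""
    mk = genotypes.markers
    a1 = mk["a1"].to_numpy() if "a1" in mk else np.full(len(mk), "A")
    a2 = mk["a2"].to_numpy() if "a2" in mk else np.full(len(mk), "B")
    with open(map_path, "w") as fh:
        for row in mk.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.id}\t0\t{row.pos}\n")
    code = {2: ("{0}", "{0}"), 1: ("{0}", "{1}"), 0: ("{1}", "{1}"),
            MISSING: ("0", "0")}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(genotypes.samples):
            fields = [str(sid), str(sid), "0", "0", "0", "-9"]
            for j, d in enumerate(genotypes.dosages[i]):
                t = code[int(d)]
                fields.append(t[0].format(a1[j], a2[j]))
                fields.append(t[1].format(a1[j], a2[j]))
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(vcf_path) -> GenotypeMatrix:
    """Read a VCF (v4.x, GT field) into a :class:`GenotypeMatrix`.

    Dosage counts the REF allele; ``|`` and ``/`` separators are both
    accepted; ``./.`` is missing.  Non-biallelic records are skipped and the
    skip count is logged and attached to the result as
    ``n_skipped_records``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    if "ID=GT" not in vcf.raw_header:
        raise GenotypeFormatError(f"{vcf_path}: no GT field in FORMAT header")
    samples = list(vcf.samples)
    if not samples:
        raise GenotypeFormatError(f"{vcf_path}: no sample columns")

    cols, chroms, ids, pos, ref, alt = [], [], [], [], [], []
    n_skipped = 0
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    to_dosage = np.array([2, 1, MISSING, 0], dtype=np.int8)
    for k, v in enumerate(vcf):
        if len(v.ALT) != 1:
            n_skipped += 1
            continue
        cols.append(to_dosage[v.gt_types])
        chroms.append(v.CHROM)
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic records", n_skipped)
    dosages = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0), np.int8)
    )
    markers = make_marker_map(chroms, ids, pos, ref, alt)
    gm = GenotypeMatrix(dosages, samples, markers)
    gm.n_skipped_records = n_skipped
    return gm


def write_vcf(genotypes: GenotypeMatrix, vcf_path) -> None:
    """Write a minimal VCF v4.2 with GT-only genotype columns."""
    mk = genotypes.markers
    a1 = mk["a1"].to_numpy() if "a1" in mk else np.full(len(mk), "A")
    a2 = mk["a2"].to_numpy() if "a2" in mk else np.full(len(mk), "C")
    gt = {2: "0/0", 1: "0/1", 0: "1/1", MISSING: "./."}
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in genotypes.chromosomes():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in genotypes.samples)
            + "\n"
        )
        for j, row in enumerate(mk.itertuples(index=False)):
            calls = "\t".join(gt[int(d)] for d in genotypes.dosages[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{a1[j]}\t{a2[j]}"
                f"\t.\t.\t.\tGT\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# Per-marker allele statistics
# ---------------------------------------------------------------------------

def allele_stats(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker allele statistics.

    Returns a DataFrame indexed like the marker map with genotype counts
    (``n_AA`` = dosage 2, ``n_Aa``, ``n_aa``, ``n_missing``), ``call_rate``,
    allele-A frequency ``freq_a`` = (2 n_AA + n_Aa) / (2 non-missing),
    ``maf`` = min(freq_a, 1 - freq_a), and an ``undefined`` flag for
    all-missing markers (frequency reported as NaN).
    """
    d = genotypes.dosages
    n = d.shape[0]
    n_aa2 = (d == 2).sum(axis=0)
    n_het = (d == 1).sum(axis=0)
    n_aa0 = (d == 0).sum(axis=0)
    n_miss = (d == MISSING).sum(axis=0)
    nonmiss = n - n_miss
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(nonmiss > 0, (2 * n_aa2 + n_het) / (2 * np.maximum(nonmiss, 1)), np.nan)
    freq = np.where(nonmiss > 0, freq, np.nan)
    maf = np.minimum(freq, 1 - freq)
    out = genotypes.markers[list(MAP_COLUMNS)].copy()
    out["n_AA"] = n_aa2
    out["n_Aa"] = n_het
    out["n_aa"] = n_aa0
    out["n_missing"] = n_miss
    out["call_rate"] = nonmiss / n if n else np.nan
    out["freq_a"] = freq
    out["maf"] = maf
    out["undefined"] = nonmiss == 0
    return out


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def write_tables(tables: dict, outdir) -> list:
    """Write named DataFrames as TSVs with one header row.

    Output is deterministic and byte-stable for identical input: floats are
    rendered with repr-level precision and row order is preserved.  Returns
    the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
        paths.append(path)
    return paths
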