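"""Readers and writers for GBS allele-count data and parentage tables.

Supported formats
-----------------
* Tassel/UNEAK HapMap ``.hmc.txt`` allele-count tables (gzip transparent):
  one row per SNP tag pair, sample cells encoded ``refCount|altCount``,
  trailing per-SNP summary columns detected by header name and skipped.
* VCF with a per-sample allelic-depth (``AD``) FORMAT field, via cyvcf2.
* A generic lossless interchange format: a pair of tab-delimited matrices
  (reference counts, alternate counts) sharing row (individual) and column
  (SNP) headers.
* Candidate-parent tables (CSV/TSV) listing each individual's role, and
  assignment reports.

Conventions: the "reference" allele is the first count in ``a|b``; a cell
with both counts zero means no reads (missing).
"""

from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AlleleCountMatrix",
    "CandidateTable",
    "read_hmc",
    "write_hmc",
    "read_vcf_counts",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_candidates",
    "write_assignments",
    "read_assignments",
    "write_grm_tsv",
    "read_grm_tsv",
    "write_grm_hdf5",
    "ASSIGNMENT_COLUMNS",
]

#: Header names of trailing per-SNP summary columns in UNEAK hmc output.
DEFAULT_HMC_SUMMARY_COLUMNS = (
    "HetCount_allele1",
    "HetCount_allele2",
    "Count_allele1",
    "Count_allele2",
    "Frequency",
)

_COUNT_TOKEN = re.compile(r"^(\d+)\|(\d+)$")


@dataclass
class AlleleCountMatrix:
    """Per-individual, per-SNP reference/alternate allele read counts.

    ``ref`` and ``alt`` are (n_individuals, n_snps) non-negative integer
    arrays.  A cell with ``ref == alt == 0`` carries no reads and is treated
    as missing everywhere downstream; total read depth is ``ref + alt``.
    """

    individual_ids: list[str]
    snp_ids: list[str]
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        n_ind, n_snp = len(self.individual_ids), len(self.snp_ids)
        if self.ref.shape != (n_ind, n_snp) or self.alt.shape != (n_ind, n_snp):
            raise ValueError(
                f"count arrays must be ({n_ind}, {n_snp}); "
                f"got ref {self.ref.shape}, alt {self.alt.shape}"
            )
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("allele counts must be non-negative")
        for name, ids in (("individual", self.individual_ids), ("SNP", self.snp_ids)):
            if len(set(ids)) != len(ids):
                dup = pd.Index(ids)[pd.Index(ids).duplicated()].tolist()
                raise ValueError(f"duplicate {name} ids: {dup[:5]}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def depth(self) -> np.ndarray:
        """Total read depth per cell."""
        return self.ref + self.alt

    def index_of(self, individual_id: str) -> int:
        try:
            return self.individual_ids.index(individual_id)
        except ValueError:
            raise KeyError(f"unknown individual id: {individual_id!r}") from None

    def subset_individuals(self, ids: list[str]) -> "AlleleCountMatrix":
        rows = [self.index_of(i) for i in ids]
        return AlleleCountMatrix(list(ids), list(self.snp_ids), self.ref[rows], self.alt[rows])

    def subset_snps(self, mask: np.ndarray) -> "AlleleCountMatrix":
        mask = np.asarray(mask)
        snp_ids = [s for s, keep in zip(self.snp_ids, mask) if keep]
        return AlleleCountMatrix(list(self.individual_ids), snp_ids, self.ref[:, mask], self.alt[:, mask])


@dataclass
class CandidateTable:
    """Offspring plus the sets of candidate sires and dams.

    IDs absent from the genotype data are kept but flagged in
    ``ungenotyped`` and excluded from matching.  ``subpop`` optionally labels
    individuals with a subpopulation (e.g. breed) used for per-subpopulation
    allele frequencies; ``recorded_sire``/``recorded_dam`` support
    verification runs against a recorded pedigree.
    """

    offspring_ids: list[str]
    sire_candidate_ids: list[str]
    dam_candidate_ids: list[str]
    subpop: dict[str, str] = field(default_factory=dict)
    recorded_sire: dict[str, str] = field(default_factory=dict)
    recorded_dam: dict[str, str] = field(default_factory=dict)
    ungenotyped: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = set(self.sire_candidate_ids) & set(self.dam_candidate_ids)
        if overlap and not getattr(self, "_allow_overlap", False):
            raise ValueError(
                f"ids appear in both sire and dam candidate sets: {sorted(overlap)[:5]}; "
                "pass allow_overlap=True to read_candidates to permit this"
            )

    def flag_ungenotyped(self, genotyped_ids: set[str]) -> None:
        all_ids = set(self.offspring_ids) | set(self.sire_candidate_ids) | set(self.dam_candidate_ids)
        self.ungenotyped = all_ids - set(genotyped_ids)

    def genotyped_sires(self) -> list[str]:
        return [i for i in self.sire_candidate_ids if i not in self.ungenotyped]

    def genotyped_dams(self) -> list[str]:
        return [i for i in self.dam_candidate_ids if i not in self.ungenotyped]


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_hmc(path, summary_columns=DEFAULT_HMC_SUMMARY_COLUMNS) -> AlleleCountMatrix:
    """Parse a Tassel/UNEAK HapMap allele-count (hmc) table.

    The file is tab-delimited with the SNP identifier in the first column,
    one ``ref|alt`` column per sample, and trailing per-SNP summary columns.
    Trailing columns whose header appears in *summary_columns* are skipped;
    an unknown trailing column that does not parse as ``int|int`` but is
    numeric is skipped with a warning rather than silently included.
    """
    summary = {c.lower() for c in summary_columns}
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: not a tab-delimited hmc file")
        lines = fh.read().splitlines()

    # identify the contiguous block of trailing summary columns
    first_data = lines[0].split("\t") if lines else None
    last_sample = len(header) - 1
    while last_sample >= 1:
        name = header[last_sample]
        if name.lower() in summary:
            last_sample -= 1
            continue
        if first_data is not None and not _COUNT_TOKEN.match(first_data[last_sample]):
            try:
                float(first_data[last_sample])
            except ValueError:
                break  # not numeric either; treat as sample and let parsing raise
            warnings.warn(
                f"{path}: trailing column {name!r} is numeric but not 'int|int'; "
                "assuming it is a per-SNP summary column and skipping it"
            )
            last_sample -= 1
            continue
        break

    sample_ids = header[1 : last_sample + 1]
    if len(set(sample_ids)) != len(sample_ids):
        dup = pd.Index(sample_ids)[pd.Index(sample_ids).duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample headers: {dup[:5]}")

    snp_ids: list[str] = []
    ref_rows, alt_rows = [], []
    for row_i, line in enumerate(lines, start=2):
        fields = line.split("\t")
        snp_ids.append(fields[0])
        ref_row = np.empty(len(sample_ids), dtype=np.int64)
        alt_row = np.empty(len(sample_ids), dtype=np.int64)
        for col_j, tok in enumerate(fields[1 : last_sample + 1]):
            m = _COUNT_TOKEN.match(tok)
            if m is None:
                raise ValueError(
                    f"{path}: malformed count token {tok!r} at line {row_i}, "
                    f"sample {sample_ids[col_j]!r} (expected 'int|int')"
                )
            ref_row[col_j] = int(m.group(1))
            alt_row[col_j] = int(m.group(2))
        ref_rows.append(ref_row)
        alt_rows.append(alt_row)

    ref = np.array(ref_rows, dtype=np.int64).T if snp_ids else np.zeros((len(sample_ids), 0), np.int64)
    alt = np.array(alt_rows, dtype=np.int64).T if snp_ids else np.zeros((len(sample_ids), 0), np.int64)
    return AlleleCountMatrix(sample_ids, snp_ids, ref, alt)


def write_hmc(counts: AlleleCountMatrix, path, summary_columns=True) -> None:
    """Write an hmc-dialect file (fixture writer; inverse of :func:`read_hmc`)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    dep = counts.depth
    with opener(path, "wt") as fh:
        header = ["rs"] + list(counts.individual_ids)
        if summary_columns:
            header += list(DEFAULT_HMC_SUMMARY_COLUMNS)
        fh.write("\t".join(header) + "\n")
        for j, snp in enumerate(counts.snp_ids):
            cells = [f"{counts.ref[i, j]}|{counts.alt[i, j]}" for i in range(counts.n_individuals)]
            row = [snp] + cells
            if summary_columns:
                tot_ref = int(counts.ref[:, j].sum())
                tot_alt = int(counts.alt[:, j].sum())
                het = int(((counts.ref[:, j] > 0) & (counts.alt[:, j] > 0)).sum())
                tot = tot_ref + tot_alt
                freq = tot_ref / tot if tot else 0.0
                row += [str(het), str(het), str(tot_ref), str(tot_alt), f"{freq:.4f}"]
            fh.write("\t".join(row) + "\n")


def read_vcf_counts(path) -> AlleleCountMatrix:
    """Read ref/alt allele depths from a VCF's per-sample ``AD`` field.

    Multiallelic sites are skipped (count reported in a warning); sites or
    cells without allelic depth become missing (``ref = alt = 0``).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples")

    snp_ids: list[str] = []
    ref_cols, alt_cols = [], []
    n_multiallelic = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multiallelic += 1
            continue
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        snp_ids.append(vid)
        ad = var.format("AD")
        if ad is None:
            ref_cols.append(np.zeros(len(samples), np.int64))
            alt_cols.append(np.zeros(len(samples), np.int64))
        else:
            ad = np.asarray(ad, dtype=np.int64)
            ad[ad < 0] = 0  # cyvcf2 encodes missing AD as negative
            ref_cols.append(ad[:, 0])
            alt_cols.append(ad[:, 1] if ad.shape[1] > 1 else np.zeros(len(samples), np.int64))
    if n_multiallelic:
        warnings.warn(f"{path}: skipped {n_multiallelic} multiallelic site(s)")
    if not snp_ids:
        warnings.warn(f"{path}: no usable biallelic sites; returning empty matrix")
        return AlleleCountMatrix(samples, [], np.zeros((len(samples), 0), np.int64), np.zeros((len(samples), 0), np.int64))
    ref = np.column_stack(ref_cols)
    alt = np.column_stack(alt_cols)
    return AlleleCountMatrix(samples, snp_ids, ref, alt)


def write_counts_tsv(counts: AlleleCountMatrix, ref_path, alt_path) -> None:
    """Write the generic interchange format: ref and alt count matrices."""
    for arr, path in ((counts.ref, ref_path), (counts.alt, alt_path)):
        pd.DataFrame(arr, index=counts.individual_ids, columns=counts.snp_ids).to_csv(
            path, sep="\t", index_label="id"
        )


def read_counts_tsv(ref_path, alt_path) -> AlleleCountMatrix:
    """Read the generic interchange format written by :func:`write_counts_tsv`."""
    ref = pd.read_csv(ref_path, sep="\t", index_col="id")
    alt = pd.read_csv(alt_path, sep="\t", index_col="id")
    if list(ref.index) != list(alt.index) or list(ref.columns) != list(alt.columns):
        raise ValueError("ref and alt matrices must share identical row and column headers")
    return AlleleCountMatrix(
        [str(i) for i in ref.index],
        [str(c) for c in ref.columns],
        ref.to_numpy(dtype=np.int64),
        alt.to_numpy(dtype=np.int64),
    )


_ROLES = {"offspring", "sire_candidate", "dam_candidate"}


def read_candidates(path, genotyped_ids=None, allow_overlap: bool = False) -> CandidateTable:
    """Read a candidate-parent table.

    Delimited (comma or tab) with columns ``id``, ``role`` and optionally
    ``subpop``, ``recorded_sire``, ``recorded_dam``.  ``role`` is one of
    ``offspring``, ``sire_candidate``, ``dam_candidate``.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    for required in ("id", "role"):
        if required not in df.columns:
            raise ValueError(f"{path}: missing required column {required!r}")

    bad = set(df["role"]) - _ROLES
    if bad:
        raise ValueError(f"{path}: unknown role token(s): {sorted(bad)}")

    offspring, sires, dams = [], [], []
    subpop: dict[str, str] = {}
    rec_sire: dict[str, str] = {}
    rec_dam: dict[str, str] = {}
    for _, row in df.iterrows():
        iid, role = row["id"], row["role"]
        if role == "offspring":
            if iid in offspring:
                raise ValueError(f"{path}: duplicated offspring row for id {iid!r}")
            offspring.append(iid)
            if row.get("recorded_sire", ""):
                rec_sire[iid] = row["recorded_sire"]
            if row.get("recorded_dam", ""):
                rec_dam[iid] = row["recorded_dam"]
        elif role == "sire_candidate":
            sires.append(iid)
        else:
            dams.append(iid)
        if row.get("subpop", ""):
            subpop[iid] = row["subpop"]

    table = CandidateTable.__new__(CandidateTable)
    table._allow_overlap = allow_overlap
    table.offspring_ids = offspring
    table.sire_candidate_ids = sires
    table.dam_candidate_ids = dams
    table.subpop = subpop
    table.recorded_sire = rec_sire
    table.recorded_dam = rec_dam
    table.ungenotyped = set()
    table.__post_init__()
    if not sires and not dams:
        warnings.warn(f"{path}: no candidate parents listed")
    if genotyped_ids is not None:
        table.flag_ungenotyped(set(genotyped_ids))
    return table


#: Deterministic column order of the assignment report.
ASSIGNMENT_COLUMNS = [
    "offspring",
    "code",
    "sire",
    "sire_r",
    "sire_emm",
    "sire_second",
    "sire_gap",
    "sire_bootstrap",
    "dam",
    "dam_r",
    "dam_emm",
    "dam_second",
    "dam_gap",
    "dam_bootstrap",
    "trio_emm",
    "rfm_minus_2fo",
    "rel_min",
    "emm_max",
    "trio_emm_max",
    "closeness_window",
    "bootstrap_min",
    "inbreeding_diff_max",
]


def write_assignments(records, path) -> None:
    """Write assignment records as a TSV report, one row per offspring."""
    rows = [rec.to_row() for rec in records]
    df = pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_assignments(path) -> pd.DataFrame:
    """Read back an assignment report written by :func:`write_assignments`."""
    return pd.read_csv(path, sep="\t")


def write_grm_tsv(grm, path) -> None:
    pd.DataFrame(grm.r, index=grm.individual_ids, columns=grm.individual_ids).to_csv(
        path, sep="\t", index_label="id"
    )


def read_grm_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")


def write_grm_hdf5(grm, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("relatedness", data=grm.r)
        f.create_dataset("n_snps", data=grm.n_snps)
        f.create_dataset(
            "individual_ids",
            data=np.array(grm.individual_ids, dtype=h5py.string_dtype()),
        )
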