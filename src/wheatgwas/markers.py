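"""Genotype containers, I/O and marker quality control.

The central container is :class:`GenotypePanel`: an accession x marker
allele-dosage matrix (0/1/2, NaN for missing) together with a genetic map
(chromosome, cM) and a collinear physical map (bp) for every marker.

Quality control mirrors standard SNP-array practice for association panels:
markers with excess missing calls or a minor allele frequency below a floor
are removed; markers with byte-identical non-missing dosage patterns are
flagged as duplicates (but not removed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "QCReport",
    "read_genotypes",
    "write_genotypes",
    "qc_filter",
    "EmptyPanelError",
]

#: sentinel used for missing dosages in the float matrix
MISSING = np.nan


class EmptyPanelError(ValueError):
    """Raised when a filter removes every marker from a panel."""


@dataclass
class GenotypePanel:
    """Accession x marker dosage matrix with genetic and physical maps.

    Parameters
    ----------
    accession_ids : list of str
    marker_ids : list of str
    dosages : ndarray, shape (n_accessions, n_markers)
        Minor/alternate allele counts in {0, 1, 2}; ``NaN`` marks missing.
    map : DataFrame indexed by marker id with columns
        ``chrom`` (str), ``cm`` (float, genetic position) and
        ``bp`` (int, physical position).
    """

    accession_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    map: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.accession_ids), len(self.marker_ids)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.marker_ids)} markers"
            )
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(self.dosages[~ok])
            raise ValueError(f"dosages must be 0/1/2/NaN; found {bad}")
        if list(self.map.index) != list(self.marker_ids):
            raise ValueError("map index must equal marker_ids, in order")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency over non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def missingness(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=0)

    def subset_markers(self, keep: np.ndarray | list) -> "GenotypePanel":
        """Return a panel restricted to the given marker ids/boolean mask (order kept)."""
        if np.asarray(keep).dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {m: i for i, m in enumerate(self.marker_ids)}
            idx = np.array([pos[m] for m in keep])
        return GenotypePanel(
            accession_ids=list(self.accession_ids),
            marker_ids=[self.marker_ids[i] for i in idx],
            dosages=self.dosages[:, idx],
            map=self.map.iloc[idx],
        )


@dataclass
class QCReport:
    """Outcome of :func:`qc_filter`."""

    removed: pd.DataFrame  # columns: marker, reason
    duplicate_groups: list[list[str]] = field(default_factory=list)
    n_input: int = 0
    n_retained: int = 0

    def to_csv(self, path) -> None:
        self.removed.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "vcf") -> GenotypePanel:
    """Read a genotype panel from VCF or a dosage-matrix CSV pair.

    ``format="vcf"`` reads GT fields from a VCF 4.x file; non-biallelic
    records are excluded with a warning stating the count.  Genetic (cM)
    positions are taken from an ``CM`` INFO key when present, else 0.

    ``format="matrix-csv"`` expects ``<path>`` to be a dosage matrix CSV
    (rows = accessions, columns = markers, NaN for missing) and
    ``<path withsuffix .map.csv>`` the map with columns
    marker, chrom, cm, bp.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "matrix-csv":
        return _read_matrix_csv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    rows = []
    dosage_cols = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        marker_ids.append(rec.ID or f"{rec.CHROM}_{rec.POS}")
        cm = rec.INFO.get("CM")
        rows.append((rec.CHROM, float(cm) if cm is not None else 0.0, rec.POS))
        gt = rec.gt_types.astype(float)  # 0,1,2 and 3=missing with gts012
        gt[gt == 3] = np.nan
        dosage_cols.append(gt)
    vcf.close()
    if n_skipped:
        warnings.warn(f"excluded {n_skipped} non-biallelic record(s)", UserWarning)
    dos = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0))
    mp = pd.DataFrame(rows, columns=["chrom", "cm", "bp"], index=marker_ids)
    mp.index.name = "marker"
    return GenotypePanel(samples, marker_ids, dos, mp)


def _map_path(path) -> str:
    p = str(path)
    return p[: -len(".csv")] + ".map.csv" if p.endswith(".csv") else p + ".map.csv"


def _read_matrix_csv(path) -> GenotypePanel:
    mat = pd.read_csv(path, index_col=0)
    mp = pd.read_csv(_map_path(path), index_col=0)
    mp = mp.loc[mat.columns]
    mp.index.name = "marker"
    return GenotypePanel(
        accession_ids=list(mat.index.astype(str)),
        marker_ids=list(mat.columns),
        dosages=mat.to_numpy(dtype=float),
        map=mp[["chrom", "cm", "bp"]].assign(chrom=mp["chrom"].astype(str)),
    )


def write_genotypes(panel: GenotypePanel, path, format: str = "vcf") -> None:
    """Write a panel as VCF (GT only, contig headers, CM INFO key) or matrix CSV."""
    if format == "vcf":
        _write_vcf(panel, path)
    elif format == "matrix-csv":
        pd.DataFrame(
            panel.dosages, index=panel.accession_ids, columns=panel.marker_ids
        ).to_csv(path)
        panel.map.to_csv(_map_path(path))
    else:
        raise ValueError(f"unknown genotype format: {format!r}")


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def _write_vcf(panel: GenotypePanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic map position (cM)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in panel.map["chrom"].unique():
            length = int(panel.map.loc[panel.map["chrom"] == chrom, "bp"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.accession_ids)
            + "\n"
        )
        for j, mid in enumerate(panel.marker_ids):
            row = panel.map.iloc[j]
            gts = "\t".join(
                "./." if np.isnan(d) else _GT_CODE[d] for d in panel.dosages[:, j]
            )
            fh.write(
                f"{row['chrom']}\t{int(row['bp'])}\t{mid}\tA\tB\t.\t.\t"
                f"CM={row['cm']:.6g}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def qc_filter(
    panel: GenotypePanel,
    max_missing: float = 0.25,
    min_maf: float = 0.05,
) -> tuple[GenotypePanel, QCReport]:
    """Remove markers failing missingness/MAF thresholds; flag duplicates.

    A retained marker has per-marker missingness <= ``max_missing`` and
    minor allele frequency (computed over non-missing calls) >= ``min_maf``.
    Markers whose non-missing dosage vectors are identical are flagged in the
    report as duplicate groups but are not removed.  Marker order is never
    changed.

    Raises
    ------
    EmptyPanelError
        if no marker survives.
    """
    if not 0 <= max_missing <= 1 or not 0 <= min_maf <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    miss = panel.missingness()
    maf = panel.maf()
    removed = []
    keep = np.ones(panel.n_markers, dtype=bool)
    for j, mid in enumerate(panel.marker_ids):
        if miss[j] > max_missing:
            removed.append((mid, "missingness"))
            keep[j] = False
        elif np.isnan(maf[j]) or maf[j] < min_maf:
            removed.append((mid, "maf"))
            keep[j] = False
    if not keep.any():
        raise EmptyPanelError("no marker passed QC")
    out = panel.subset_markers(keep)

    # duplicate-pattern detection among retained markers: identical dosage
    # vectors on the positions where both are non-missing AND identical
    # missingness pattern (byte-identical columns).
    groups: dict[bytes, list[str]] = {}
    arr = out.dosages
    for j, mid in enumerate(out.marker_ids):
        key = arr[:, j].tobytes()
        groups.setdefault(key, []).append(mid)
    dup_groups = [g for g in groups.values() if len(g) > 1]

    report = QCReport(
        removed=pd.DataFrame(removed, columns=["marker", "reason"]),
        duplicate_groups=dup_groups,
        n_input=panel.n_markers,
        n_retained=out.n_markers,
    )
    return out, report
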