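"""Reading Visium-style inputs and applying spot/gene/SNP quality filters.

The expected on-disk layout mirrors the 10x / cellsnp-lite conventions:

* gene counts: ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``
* allele counts: two MatrixMarket matrices (haplotype-1 counts and total
  counts at known germline heterozygous SNPs) + a SNP table with CHROM,
  POS and the population-phasing flag (``0|1`` or ``1|0``)
* spot coordinates: CSV with ``barcode,x,y`` (or the tissue_positions
  dialect ``barcode,...,row,col``)
* gene annotation: 4+-column TSV (gene, chrom, start, end [, ig, hla])
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

__all__ = [
    "RawBundle",
    "FilterReport",
    "read_bundle",
    "write_bundle_inputs",
    "filter_spots",
    "filter_genes",
    "filter_snps",
    "lof_outlier_genes",
]

CHROM_ORDER = {f"chr{i}": i for i in range(1, 23)} | {"chrX": 23, "chrY": 24}


def _chrom_key(c: str) -> int:
    c = c if str(c).startswith("chr") else f"chr{c}"
    return CHROM_ORDER.get(c, 100)


@dataclass
class RawBundle:
    """Spot-level inputs: transcripts, phased allele counts, coordinates.

    ``Y0[g, s]`` counts UMIs supporting population-phasing haplotype 1 at
    SNP ``g`` in spot ``s``; ``D0`` the total allele-informative UMIs.
    All matrices share the spot axis with ``S`` and ``slice_id``.
    """

    X0: np.ndarray  # gene x spot
    Y0: np.ndarray  # snp x spot, haplotype-1 counts
    D0: np.ndarray  # snp x spot, total counts
    S: np.ndarray  # spot x 2
    slice_id: np.ndarray  # spot
    barcodes: np.ndarray  # spot
    snp_index: pd.DataFrame  # chrom, pos, phase_flag
    gene_index: pd.DataFrame  # gene, chrom, start, end, ig, hla

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        n_spots = self.X0.shape[1]
        if not (
            self.Y0.shape[1] == self.D0.shape[1] == self.S.shape[0]
            == len(self.slice_id) == len(self.barcodes) == n_spots
        ):
            raise ValueError("spot axes of X0/Y0/D0/S/slice_id/barcodes disagree")
        if self.Y0.shape != self.D0.shape:
            raise ValueError("Y0 and D0 shapes differ")
        if len(self.snp_index) != self.Y0.shape[0]:
            raise ValueError("snp_index length != allele matrix rows")
        if len(self.gene_index) != self.X0.shape[0]:
            raise ValueError("gene_index length != gene matrix rows")
        if (self.Y0 > self.D0).any():
            raise ValueError("haplotype-1 counts exceed total counts (Y0 > D0)")
        if (self.X0 < 0).any() or (self.Y0 < 0).any() or (self.D0 < 0).any():
            raise ValueError("negative counts")
        keys = list(zip(self.snp_index["chrom"].map(_chrom_key), self.snp_index["pos"]))
        if keys != sorted(keys):
            raise ValueError("snp_index not sorted by (chromosome, position)")

    @property
    def n_spots(self) -> int:
        return self.X0.shape[1]

    @property
    def n_genes(self) -> int:
        return self.X0.shape[0]

    @property
    def n_snps(self) -> int:
        return self.Y0.shape[0]

    def subset(self, spots=None, genes=None, snps=None) -> "RawBundle":
        spots = np.arange(self.n_spots) if spots is None else np.asarray(spots)
        genes = np.arange(self.n_genes) if genes is None else np.asarray(genes)
        snps = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        return RawBundle(
            X0=self.X0[np.ix_(genes, spots)],
            Y0=self.Y0[np.ix_(snps, spots)],
            D0=self.D0[np.ix_(snps, spots)],
            S=self.S[spots],
            slice_id=self.slice_id[spots],
            barcodes=self.barcodes[spots],
            snp_index=self.snp_index.iloc[snps].reset_index(drop=True),
            gene_index=self.gene_index.iloc[genes].reset_index(drop=True),
        )


@dataclass
class FilterReport:
    spots_removed: dict = field(default_factory=dict)
    genes_removed: dict = field(default_factory=dict)
    snps_removed: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    def summary(self) -> str:
        return (
            f"removed {len(self.spots_removed)} spots, "
            f"{len(self.genes_removed)} genes, {len(self.snps_removed)} SNPs"
        )


# ---------------------------------------------------------------- reading


def _read_mtx(path: Path) -> np.ndarray:
    return np.asarray(mmread(str(path)).todense()).astype(np.int64)


def _read_positions(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "x" in cols and "y" in cols:
        return pd.DataFrame(
            {"barcode": df[cols["barcode"]], "x": df[cols["x"]], "y": df[cols["y"]]}
        )
    # tissue_positions dialect: barcode,in_tissue,array_row,array_col,px_row,px_col
    bc = df.columns[0]
    row = cols.get("array_row", df.columns[-2])
    col = cols.get("array_col", df.columns[-1])
    return pd.DataFrame({"barcode": df[bc], "x": df[col], "y": df[row]})


def _read_annotation(path: Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff", ".gff3"}:
        rows = []
        for line in path.read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if f[2] != "gene":
                continue
            attrs = dict(
                kv.strip().split(" ", 1) for kv in f[8].rstrip(";").split(";") if kv.strip()
            )
            name = attrs.get("gene_name", attrs.get("gene_id", "")).strip('"')
            rows.append((name, f[0], int(f[3]), int(f[4])))
        ann = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])
        ann["ig"] = ann["gene"].str.match(r"^IG[HKL]").fillna(False)
        ann["hla"] = ann["gene"].str.startswith("HLA-").fillna(False)
        return ann
    ann = pd.read_csv(path, sep="\t")
    ann.columns = [c.lower() for c in ann.columns]
    for flag in ("ig", "hla"):
        if flag not in ann.columns:
            ann[flag] = False
        ann[flag] = ann[flag].astype(bool)
    return ann[["gene", "chrom", "start", "end", "ig", "hla"]]


def _read_snp_table(path: Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        rows = []
        for line in path.read_text().splitlines():
            if line.startswith("#") or not line:
                continue
            f = line.split("\t")
            gt = f[9].split(":")[0] if len(f) > 9 else "0|1"
            rows.append((f[0], int(f[1]), 1 if gt.startswith("1") else 0))
        return pd.DataFrame(rows, columns=["chrom", "pos", "phase_flag"])
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    if "phase" in df.columns and "phase_flag" not in df.columns:
        df["phase_flag"] = df["phase"].map({"0|1": 0, "1|0": 1}).fillna(df["phase"]).astype(int)
    return df[["chrom", "pos", "phase_flag"]].astype({"pos": int, "phase_flag": int})


def read_bundle(
    counts_dir,
    alleles_dir,
    positions: dict | str | Path,
    annotation,
) -> RawBundle:
    """Assemble a :class:`RawBundle` from on-disk inputs.

    ``positions`` maps slice label -> coordinate CSV; a single path is
    treated as one slice named ``"s0"``.  Barcodes are restricted to the
    intersection of the gene-count and allele-count inputs; coordinate
    and count matrices across slices are concatenated along the spot axis.
    """
    counts_dir, alleles_dir = Path(counts_dir), Path(alleles_dir)
    for p in (counts_dir / "matrix.mtx", alleles_dir / "hap1.mtx", alleles_dir / "total.mtx"):
        if not p.exists():
            raise FileNotFoundError(p)

    X = _read_mtx(counts_dir / "matrix.mtx")
    genes = pd.read_csv(counts_dir / "features.tsv", sep="\t", header=None)[0].to_numpy()
    bc_x = pd.read_csv(counts_dir / "barcodes.tsv", sep="\t", header=None)[0].to_numpy()
    Y = _read_mtx(alleles_dir / "hap1.mtx")
    D = _read_mtx(alleles_dir / "total.mtx")
    bc_a = pd.read_csv(alleles_dir / "barcodes.tsv", sep="\t", header=None)[0].to_numpy()
    snp_index = _read_snp_table(
        alleles_dir / ("snps.vcf" if (alleles_dir / "snps.vcf").exists() else "snps.tsv")
    )
    if X.shape[1] != len(bc_x):
        raise ValueError("gene matrix columns != barcode count")
    if Y.shape != D.shape or Y.shape[1] != len(bc_a):
        raise ValueError("allele matrix dimensions malformed")

    if isinstance(positions, (str, Path)):
        positions = {"s0": positions}
    pos_frames = []
    for slab, path in positions.items():
        df = _read_positions(Path(path))
        df["slice"] = slab
        pos_frames.append(df)
    pos = pd.concat(pos_frames, ignore_index=True)

    keep = [b for b in pos["barcode"] if b in set(bc_x) and b in set(bc_a)]
    if not keep:
        raise ValueError("no overlapping barcodes between count, allele and position inputs")
    ix_x = pd.Index(bc_x).get_indexer(keep)
    ix_a = pd.Index(bc_a).get_indexer(keep)
    pos = pos.set_index("barcode").loc[keep]

    ann = _read_annotation(annotation)
    ann = ann.set_index("gene").reindex(genes).reset_index()
    ann[["start", "end"]] = ann[["start", "end"]].fillna(-1).astype(int)
    ann["chrom"] = ann["chrom"].fillna("un")
    ann[["ig", "hla"]] = ann[["ig", "hla"]].fillna(False).astype(bool)

    order = np.lexsort((snp_index["pos"], snp_index["chrom"].map(_chrom_key)))
    return RawBundle(
        X0=X[:, ix_x],
        Y0=Y[order][:, ix_a],
        D0=D[order][:, ix_a],
        S=pos[["x", "y"]].to_numpy(float),
        slice_id=pos["slice"].to_numpy(),
        barcodes=np.asarray(keep),
        snp_index=snp_index.iloc[order].reset_index(drop=True),
        gene_index=ann,
    )


def write_bundle_inputs(bundle: RawBundle, out_dir) -> dict:
    """Emit a bundle in exactly the file dialects :func:`read_bundle` accepts."""
    out = Path(out_dir)
    counts, alleles = out / "counts", out / "alleles"
    counts.mkdir(parents=True, exist_ok=True)
    alleles.mkdir(parents=True, exist_ok=True)
    mmwrite(str(counts / "matrix.mtx"), csr_matrix(bundle.X0))
    pd.Series(bundle.gene_index["gene"]).to_csv(
        counts / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(bundle.barcodes).to_csv(counts / "barcodes.tsv", sep="\t", header=False, index=False)
    mmwrite(str(alleles / "hap1.mtx"), csr_matrix(bundle.Y0))
    mmwrite(str(alleles / "total.mtx"), csr_matrix(bundle.D0))
    pd.Series(bundle.barcodes).to_csv(alleles / "barcodes.tsv", sep="\t", header=False, index=False)
    bundle.snp_index.to_csv(alleles / "snps.tsv", sep="\t", index=False)
    bundle.gene_index.to_csv(out / "annotation.tsv", sep="\t", index=False)
    positions = {}
    for slab in pd.unique(bundle.slice_id):
        mask = bundle.slice_id == slab
        df = pd.DataFrame(
            {"barcode": bundle.barcodes[mask], "x": bundle.S[mask, 0], "y": bundle.S[mask, 1]}
        )
        p = out / f"positions_{slab}.csv"
        df.to_csv(p, index=False)
        positions[slab] = p
    return {
        "counts_dir": counts,
        "alleles_dir": alleles,
        "positions": positions,
        "annotation": out / "annotation.tsv",
    }


# --------------------------------------------------------------- filtering


def filter_spots(bundle: RawBundle, min_umi: int = 50, min_snp_umi: int = 50):
    """Drop spots with too few total UMIs or too few SNP-covering UMIs.

    The default of 50 for both thresholds matches typical Visium practice
    for this pipeline.
    """
    if min_umi < 0 or min_snp_umi < 0:
        raise ValueError("thresholds must be nonnegative")
    umi = bundle.X0.sum(axis=0)
    snp_umi = bundle.D0.sum(axis=0)
    keep = (umi >= min_umi) & (snp_umi >= min_snp_umi)
    if not keep.any():
        raise ValueError("all spots removed; lower --min-umi / --min-snp-umi")
    report = FilterReport(thresholds={"min_umi": min_umi, "min_snp_umi": min_snp_umi})
    for s in np.where(~keep)[0]:
        reasons = []
        if umi[s] < min_umi:
            reasons.append(f"total UMIs {umi[s]} < {min_umi}")
        if snp_umi[s] < min_snp_umi:
            reasons.append(f"SNP UMIs {snp_umi[s]} < {min_snp_umi}")
        report.spots_removed[str(bundle.barcodes[s])] = "; ".join(reasons)
    return bundle.subset(spots=np.where(keep)[0]), report


def lof_outlier_genes(log_totals: np.ndarray, contamination: float = 0.005) -> np.ndarray:
    """Default outlier scorer: local outlier factor on log total expression.

    Flags only high-expression outliers (the quality concern is genes with
    implausibly high counts, not lowly expressed ones).
    """
    from sklearn.neighbors import LocalOutlierFactor

    n = len(log_totals)
    if n < 10 or contamination <= 0:
        return np.zeros(n, dtype=bool)
    lof = LocalOutlierFactor(
        n_neighbors=min(20, n - 1), contamination=min(contamination, 0.5)
    )
    flag = lof.fit_predict(log_totals.reshape(-1, 1)) == -1
    return flag & (log_totals > np.median(log_totals))


def filter_genes(
    bundle: RawBundle,
    min_frac_spots: float = 0.005,
    outlier_detector=lof_outlier_genes,
):
    """Drop lowly expressed, outlier-high, and immunoglobulin/HLA genes.

    A gene is "expressed" in a spot when its count is positive; genes
    expressed in fewer than ``min_frac_spots`` of spots (default 0.5%) are
    removed.  ``outlier_detector`` maps per-gene log total expression to a
    boolean flag; the default is a local-outlier-factor scorer.
    """
    if not 0 <= min_frac_spots <= 1:
        raise ValueError("min_frac_spots must lie in [0, 1]")
    frac = (bundle.X0 > 0).mean(axis=1)
    totals = bundle.X0.sum(axis=1)
    out_flag = outlier_detector(np.log1p(totals.astype(float)))
    ig = bundle.gene_index["ig"].to_numpy(bool)
    hla = bundle.gene_index["hla"].to_numpy(bool)
    keep = (frac >= min_frac_spots) & ~out_flag & ~ig & ~hla
    report = FilterReport(thresholds={"min_frac_spots": min_frac_spots})
    for g in np.where(~keep)[0]:
        reasons = []
        if frac[g] < min_frac_spots:
            reasons.append(f"expressed in {frac[g]:.4f} < {min_frac_spots} of spots")
        if out_flag[g]:
            reasons.append("expression outlier")
        if ig[g]:
            reasons.append("immunoglobulin")
        if hla[g]:
            reasons.append("HLA region")
        report.genes_removed[str(bundle.gene_index["gene"].iloc[g])] = "; ".join(reasons)
    if not keep.any():
        warnings.warn("all genes removed by filters")
    return bundle.subset(genes=np.where(keep)[0]), report


def filter_snps(bundle: RawBundle):
    """Keep SNPs inside a retained, non-HLA gene interval (drop intergenic/HLA)."""
    ann = bundle.gene_index
    keep = np.zeros(bundle.n_snps, dtype=bool)
    hla_hit = np.zeros(bundle.n_snps, dtype=bool)
    for chrom, sub in ann.groupby("chrom"):
        in_chrom = (bundle.snp_index["chrom"] == chrom).to_numpy()
        if not in_chrom.any():
            continue
        pos = bundle.snp_index.loc[in_chrom, "pos"].to_numpy()
        genic = np.zeros(len(pos), dtype=bool)
        in_hla = np.zeros(len(pos), dtype=bool)
        for _, row in sub.iterrows():
            inside = (pos >= row["start"]) & (pos <= row["end"])
            if row["hla"]:
                in_hla |= inside
            else:
                genic |= inside
        keep[in_chrom] = genic
        hla_hit[in_chrom] = in_hla
    keep &= ~hla_hit
    report = FilterReport()
    for g in np.where(~keep)[0]:
        reason = "HLA region" if hla_hit[g] else "intergenic"
        key = f"{bundle.snp_index['chrom'].iloc[g]}:{bundle.snp_index['pos'].iloc[g]}"
        report.snps_removed[key] = reason
    return bundle.subset(snps=np.where(keep)[0]), report
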