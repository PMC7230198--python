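"""Readers, writers and the SNP filtering rules of the pipeline.

Conventions: internal coordinates are 1-based inclusive (the VCF/GFF
convention); BED input is converted from 0-based half-open on read and
exceptional-change regions are emitted as BED (0-based half-open).
PHRED-scaled PL values are converted to linear likelihoods as 10^(-PL/10)
and renormalized per individual, preserving ties.  Readers reject malformed
input instead of silently coercing it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .popfreq import GenotypeLikelihoods

__all__ = [
    "VariantTable",
    "GeneAnnotation",
    "read_vcf_genotype_likelihoods",
    "filter_variants",
    "read_gff_genes",
    "read_bed_genes",
    "write_vcf",
    "write_freq_table",
    "read_freq_table",
    "write_regions_bed",
    "write_trait_table",
    "read_trait_table",
    "write_gff_genes",
    "write_count_matrix",
    "read_count_matrix",
]


@dataclass
class VariantTable:
    """Per-site summaries used by the SNP filters.

    ``table`` columns: scaffold, position, ref, alt, mean_depth,
    alt_reads, maf, missingness, chrom_class.  ``depths`` is the per-site x
    per-individual read-depth matrix.
    """

    table: pd.DataFrame
    depths: np.ndarray


@dataclass
class GeneAnnotation:
    """Gene intervals with optional class labels.

    ``table`` columns: gene_id, scaffold, start, end (1-based inclusive),
    strand, classes (frozenset of class-label strings).
    """

    table: pd.DataFrame


def _phred_to_linear(pl: np.ndarray) -> np.ndarray:
    lin = np.power(10.0, -np.asarray(pl, dtype=float) / 10.0)
    return lin / lin.sum(axis=-1, keepdims=True)


def read_vcf_genotype_likelihoods(
    path: str, chrom_class_map: dict[str, str] | None = None
) -> tuple[GenotypeLikelihoods, VariantTable]:
    """Read a VCF with PL (or GL) FORMAT fields.

    Returns linear, per-individual-renormalized genotype likelihoods with a
    missingness mask, plus a :class:`VariantTable` for filtering.  Records
    without PL/GL raise a format error citing the offending site.
    ``chrom_class_map`` maps scaffold name to {autosome, X, other};
    unmapped scaffolds are labelled autosome.
    """
    chrom_class_map = chrom_class_map or {}
    vcf = VCF(path)
    lik_rows, miss_rows, site_rows, depth_rows = [], [], [], []
    def _fmt(var, key):
        try:
            return var.format(key)
        except KeyError:  # field absent from the header entirely
            return None

    for var in vcf:
        gl = _fmt(var, "GL")
        pl = _fmt(var, "PL")
        if gl is not None:
            # GL is log10-scaled and float-valued; preferred over PL when
            # both are present since integer PLs quantize the likelihoods
            gl = np.asarray(gl, dtype=float)
            missing = ~np.all(np.isfinite(gl), axis=1)
            gl_safe = np.where(missing[:, None], 0.0, gl)
            lin = np.power(10.0, gl_safe - gl_safe.max(axis=1, keepdims=True))
            lin = lin / lin.sum(axis=1, keepdims=True)
        elif pl is not None:
            pl = np.asarray(pl, dtype=float)
            missing = np.any(pl < 0, axis=1) | np.any(~np.isfinite(pl), axis=1)
            pl_safe = np.where(missing[:, None], 0.0, pl)
            lin = _phred_to_linear(pl_safe)
        else:
            raise ValueError(f"record {var.CHROM}:{var.POS} has neither PL nor GL")
        lin = np.where(missing[:, None], 1.0 / 3.0, lin)

        dp = _fmt(var, "DP")
        dp = (
            np.clip(np.asarray(dp, dtype=float)[:, 0], 0, None)
            if dp is not None
            else np.full(lin.shape[0], np.nan)
        )
        ad = _fmt(var, "AD")
        alt_reads = (
            float(np.nansum(np.clip(np.asarray(ad, dtype=float)[:, 1], 0, None)))
            if ad is not None
            else np.nan
        )
        tot_reads = float(np.nansum(dp)) if np.isfinite(dp).any() else np.nan
        if alt_reads is not np.nan and tot_reads and tot_reads > 0:
            f = alt_reads / tot_reads
            maf = min(f, 1.0 - f)
        else:
            maf = np.nan
        lik_rows.append(lin)
        miss_rows.append(missing)
        depth_rows.append(dp)
        site_rows.append(
            {
                "scaffold": var.CHROM,
                "position": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
                "mean_depth": float(np.nanmean(dp)),
                "alt_reads": alt_reads,
                "maf": maf,
                "missingness": float(np.mean(missing)),
                "chrom_class": chrom_class_map.get(var.CHROM, "autosome"),
            }
        )
    if not site_rows:
        raise ValueError(f"no variant records in {path}")
    sites = pd.DataFrame(site_rows)
    gl_obj = GenotypeLikelihoods(
        sites=sites[["scaffold", "position", "chrom_class"]].copy(),
        likelihoods=np.stack(lik_rows),
        missing=np.stack(miss_rows),
    )
    vt = VariantTable(table=sites, depths=np.stack(depth_rows))
    return gl_obj, vt


def filter_variants(
    vt: VariantTable,
    min_mean_coverage: float = 2.0,
    min_alt_reads: int = 10,
    max_missing: float = 0.25,
    min_maf: float = 0.005,
    max_coverage: str | float = "mean+2sd",
) -> np.ndarray:
    """Apply the SNP retention rules; returns a boolean keep-mask.

    A site is retained iff mean per-individual depth >= ``min_mean_coverage``,
    non-reference read support >= ``min_alt_reads``, missingness <=
    ``max_missing``, minor allele frequency >= ``min_maf`` and mean depth
    does not exceed the coverage cap (default: across-site mean + 2 s.d.,
    guarding against collapsed paralogs).  Read-level mapping-quality
    filtering happens upstream in variant calling and is assumed done.
    """
    t = vt.table
    if len(t) == 0:
        raise ValueError("empty variant table")
    keep = (
        (t["mean_depth"] >= min_mean_coverage)
        & (t["alt_reads"] >= min_alt_reads)
        & (t["missingness"] <= max_missing)
        & (t["maf"] >= min_maf)
    )
    if max_coverage == "mean+2sd":
        cap = t["mean_depth"].mean() + 2.0 * t["mean_depth"].std(ddof=0)
    else:
        cap = float(max_coverage)
    keep &= t["mean_depth"] <= cap
    return keep.to_numpy()


def read_gff_genes(
    path: str,
    feature: str = "gene",
    class_files: dict[str, str] | None = None,
) -> GeneAnnotation:
    """Read gene intervals from GFF3 (1-based inclusive coordinates).

    ``class_files`` maps a class label (e.g. "P450") to a file with one
    gene ID per line; matching genes get the label attached.  Duplicate
    gene IDs and malformed lines raise errors citing the line number.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line {ln}: expected 9 fields")
            scaf, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != feature:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"malformed GFF3 line {ln}: bad coordinates") from exc
            if start_i > end_i:
                raise ValueError(f"malformed GFF3 line {ln}: start > end")
            gid = None
            for field in attrs.split(";"):
                key, _, val = field.strip().partition("=")
                if key in ("ID", "gene_id", "Name") and gid is None:
                    gid = val
            if gid is None:
                raise ValueError(f"GFF3 line {ln}: no ID attribute")
            rows.append((gid, scaf, start_i, end_i, strand))
    tab = pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end", "strand"])
    if tab["gene_id"].duplicated().any():
        dup = tab.loc[tab["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene ID: {dup}")
    tab["classes"] = [frozenset()] * len(tab)
    if class_files:
        memberships = {}
        for label, cpath in class_files.items():
            with open(cpath) as fh:
                for gid in (g.strip() for g in fh):
                    if gid:
                        memberships.setdefault(gid, set()).add(label)
        tab["classes"] = [
            frozenset(memberships.get(g, ())) for g in tab["gene_id"]
        ]
    return GeneAnnotation(table=tab)


def read_bed_genes(path: str) -> GeneAnnotation:
    """Read gene intervals from BED (0-based half-open -> 1-based inclusive)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {ln}")
            scaf, start, end = parts[0], int(parts[1]), int(parts[2])
            gid = parts[3] if len(parts) > 3 else f"bed_{ln}"
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((gid, scaf, start + 1, end, strand))
    tab = pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end", "strand"])
    if tab["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ID in BED input")
    tab["classes"] = [frozenset()] * len(tab)
    return GeneAnnotation(table=tab)


# ---------------------------------------------------------------------------
# writers (all plain text; simulated data round-trips through the readers)


def write_vcf(
    path: str,
    scaffolds: np.ndarray,
    positions: np.ndarray,
    likelihoods: np.ndarray,
    depths: np.ndarray | None = None,
    alt_reads: np.ndarray | None = None,
    sample_names: list[str] | None = None,
    missing: np.ndarray | None = None,
) -> None:
    """Write simulated genotype likelihoods as a VCF with PL/DP/AD fields."""
    n_sites, n_ind, _ = likelihoods.shape
    if sample_names is None:
        sample_names = [f"ind{i}" for i in range(n_ind)]
    if missing is None:
        missing = np.zeros((n_sites, n_ind), dtype=bool)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hostadapt-simdata\n")
        for scaf in pd.unique(np.asarray(scaffolds)):
            fh.write(f"##contig=<ID={scaf}>\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
            '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled '
            'genotype likelihoods">\n'
            '##FORMAT=<ID=GL,Number=G,Type=Float,Description="Log10-scaled '
            'genotype likelihoods">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for i in range(n_sites):
            cells = []
            for j in range(n_ind):
                if missing[i, j]:
                    cells.append("./.:.:.:.:.")
                    continue
                lik = np.maximum(likelihoods[i, j], 1e-300)
                log10 = np.log10(lik) - np.log10(lik.max())
                pl = np.minimum(np.round(-10.0 * log10), 255).astype(int)
                gl_txt = ",".join(f"{v:.8f}" for v in log10)
                dp = int(depths[i, j]) if depths is not None else 0
                ar = int(alt_reads[i, j]) if alt_reads is not None else 0
                cells.append(
                    f"./.:{dp}:{dp - ar},{ar}:{pl[0]},{pl[1]},{pl[2]}:{gl_txt}"
                )
            fh.write(
                f"{scaffolds[i]}\t{positions[i]}\t.\tA\tG\t.\tPASS\t.\t"
                "GT:DP:AD:PL:GL\t" + "\t".join(cells) + "\n"
            )


def write_freq_table(path: str, sites: pd.DataFrame, est) -> None:
    """Write the popfreq output table (scaffold, position, chrom_class,
    p_mean, p_sd, n_called)."""
    out = sites[["scaffold", "position", "chrom_class"]].copy()
    out["p_mean"] = est.posterior_mean
    out["p_sd"] = est.posterior_sd
    out["n_called"] = est.n_called
    with open(path, "w") as fh:
        fh.write("# hostadapt allele-frequency table\n")
        out.to_csv(fh, sep="\t", index=False)


def read_freq_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_regions_bed(path: str, regions: pd.DataFrame) -> None:
    """Write exceptional-change regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for _, row in regions.iterrows():
            fh.write(
                f"{row['scaffold']}\t{row['start'] - 1}\t{row['end']}\t"
                f"n_snps={row['n_snps']}\n"
            )


def write_trait_table(path: str, ids, family, weight, dev_time) -> None:
    pd.DataFrame(
        {"id": ids, "family": family, "weight_mg": weight, "devtime_days": dev_time}
    ).to_csv(path, sep="\t", index=False)


def read_trait_table(path: str) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", comment="#")
    req = {"id", "family", "weight_mg", "devtime_days"}
    if not req.issubset(t.columns):
        raise ValueError(f"trait table needs columns {sorted(req)}")
    return t


def write_gff_genes(path: str, genes: pd.DataFrame) -> None:
    """Write gene intervals as GFF3 (columns gene_id, scaffold, start, end
    and optionally strand)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in genes.iterrows():
            strand = row.get("strand", "+")
            fh.write(
                f"{row['scaffold']}\thostadapt\tgene\t{row['start']}\t"
                f"{row['end']}\t.\t{strand}\t.\tID={row['gene_id']}\n"
            )


def write_count_matrix(path: str, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_count_matrix(path: str) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", index_col=0)
    if (t.dtypes == object).any():
        raise ValueError("count matrix contains non-numeric entries")
    return t
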