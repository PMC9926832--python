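"""Standard-format I/O: VCF (calls and posteriors), BED exclusions, TSV tables.

Coordinate conventions: VCF and TSV outputs are 1-based; BED is 0-based
half-open. Genotype posteriors round-trip through VCF with GT (argmax
hard call), GP (three posteriors, 4 decimals) and DS (dosage, 4 decimals).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .impute import GenotypePosterior, SiteInfo, Sites
from .popcall import ExclusionRegions, SiteCall
from .synthetic_cohort import BASES, ReadPileup


def _base_header(chrom: str, length: int) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={chrom},length={length}>")
    return header


def write_calls_vcf(
    path: str | Path, calls: Sequence[SiteCall], contig_length: int = 250_000_000
) -> None:
    """One record per call; FILTER carries the calling status, INFO the
    pooled AF estimate (AF), LRT statistic (LRT) and its p-value (LRTP)."""
    if not calls:
        chrom = "1"
    else:
        chrom = calls[0].chrom
    header = _base_header(chrom, contig_length)
    header.add_line('##INFO=<ID=AF,Number=1,Type=Float,Description="Pooled alt AF MLE">')
    header.add_line('##INFO=<ID=LRT,Number=1,Type=Float,Description="LRT statistic">')
    header.add_line('##INFO=<ID=LRTP,Number=1,Type=Float,Description="LRT p-value">')
    for flt in ("NOT_SIGNIFICANT", "MULTIALLELIC", "REGION_FILTERED"):
        header.add_line(f'##FILTER=<ID={flt},Description="{flt.lower()}">')
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for c in calls:
            rec = vf.new_record(
                contig=c.chrom,
                start=c.pos - 1,
                stop=c.pos,
                alleles=(c.ref_base, c.alt_base),
            )
            rec.info["AF"] = float(c.f_hat)
            rec.info["LRT"] = float(c.lrt_stat)
            rec.info["LRTP"] = float(c.p_value)
            rec.filter.add(c.status)
            vf.write(rec)


def write_posteriors_vcf(
    path: str | Path,
    sites: Sites,
    post: GenotypePosterior,
    site_info: SiteInfo,
    sample_names: Sequence[str] | None = None,
    contig_length: int = 250_000_000,
    gp_tol: float = 1e-3,
) -> None:
    """Imputed genotypes as VCF with GT/GP/DS and INFO keys EAF and INFO."""
    gp = post.gp
    S, M, _ = gp.shape
    if np.any(np.abs(gp.sum(axis=2) - 1.0) > gp_tol):
        raise ValueError("GP triples must sum to 1 within tolerance")
    if sample_names is None:
        sample_names = [f"S{i:05d}" for i in range(S)]
    header = _base_header(sites.chrom, contig_length)
    header.add_line('##INFO=<ID=EAF,Number=1,Type=Float,Description="Estimated alt AF">')
    header.add_line('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation INFO score">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Hard-call genotype">')
    header.add_line('##FORMAT=<ID=GP,Number=3,Type=Float,Description="Genotype posterior">')
    header.add_line('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt dosage">')
    for name in sample_names:
        header.add_sample(name)
    hard = post.hard_calls
    dosage = post.dosage
    gt_map = [(0, 0), (0, 1), (1, 1)]
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for m in range(M):
            rec = vf.new_record(
                contig=sites.chrom,
                start=int(sites.positions[m]) - 1,
                stop=int(sites.positions[m]),
                alleles=(BASES[sites.ref[m]], BASES[sites.alt[m]]),
            )
            rec.info["EAF"] = float(site_info.est_af[m])
            rec.info["INFO"] = float(site_info.info_score[m])
            for i, name in enumerate(sample_names):
                smp = rec.samples[name]
                smp["GT"] = gt_map[hard[i, m]]
                smp["GP"] = tuple(round(float(x), 4) for x in gp[i, m])
                smp["DS"] = round(float(dosage[i, m]), 4)
            vf.write(rec)


def read_posteriors_vcf(path: str | Path):
    """Read a posterior VCF back into (Sites, GenotypePosterior, SiteInfo)."""
    positions, ref, alt, eaf, info = [], [], [], [], []
    gps = []
    chrom = "1"
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            chrom = rec.contig
            positions.append(rec.pos)
            ref.append(BASES.index(rec.ref))
            alt.append(BASES.index(rec.alts[0]))
            eaf.append(float(rec.info["EAF"]))
            info.append(float(rec.info["INFO"]))
            gps.append([list(rec.samples[s]["GP"]) for s in samples])
    gp = np.transpose(np.asarray(gps, dtype=float), (1, 0, 2))
    sites = Sites(
        chrom,
        np.asarray(positions, dtype=np.int64),
        np.asarray(ref, dtype=np.uint8),
        np.asarray(alt, dtype=np.uint8),
    )
    return sites, GenotypePosterior(gp), SiteInfo(np.asarray(eaf), np.asarray(info))


def read_bed(path: str | Path) -> ExclusionRegions:
    """Read a 3+ column BED (0-based half-open) into exclusion regions.

    Overlapping intervals are accepted and merged; end <= start raises with
    the offending line number.
    """
    raw = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            raw.append((chrom, start, end))
    return ExclusionRegions.from_list(raw)


def write_bed(path: str | Path, regions: ExclusionRegions) -> None:
    with open(path, "w") as fh:
        fh.write("# 0-based half-open exclusion intervals\n")
        for chrom in sorted(regions.intervals):
            for start, end in regions.intervals[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\n")


PILEUP_COLUMNS = ["sample_id", "chrom", "pos", "base", "error_prob"]


def write_pileup_tsv(
    path: str | Path, pileup: ReadPileup, chrom: str, positions: np.ndarray
) -> None:
    """Documented flat pileup format: sample_id, chrom, pos (1-based), base,
    error_prob; one row per read."""
    df = pd.DataFrame(
        {
            "sample_id": pileup.sample_idx,
            "chrom": chrom,
            "pos": np.asarray(positions)[pileup.site_idx],
            "base": [BASES[b] for b in pileup.base],
            "error_prob": pileup.error_prob,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_pileup_tsv(
    path: str | Path, positions: np.ndarray, n_samples: int
) -> ReadPileup:
    df = pd.read_csv(path, sep="\t")
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup TSV missing columns {sorted(missing)}")
    pos_to_idx = {int(p): i for i, p in enumerate(np.asarray(positions))}
    site_idx = df["pos"].map(pos_to_idx)
    if site_idx.isna().any():
        raise ValueError("pileup TSV contains positions outside the site set")
    return ReadPileup(
        df["sample_id"].to_numpy(np.int32),
        site_idx.to_numpy(np.int32),
        np.array([BASES.index(b) for b in df["base"]], dtype=np.uint8),
        df["error_prob"].to_numpy(float),
        n_samples,
        len(positions),
    )


def qc_table_frame(sites: Sites, records, est_af: np.ndarray, survivors) -> pd.DataFrame:
    surv = set(int(s) for s in survivors)
    return pd.DataFrame(
        {
            "chrom": sites.chrom,
            "pos": sites.positions,
            "ref": [BASES[b] for b in sites.ref],
            "alt": [BASES[b] for b in sites.alt],
            "EAF": est_af,
            "MAF": [r.maf for r in records],
            "INFO": [r.info_score for r in records],
            "HWE_P": [r.hwe_p for r in records],
            "KNOWN": [r.known_flag for r in records],
            "PASS": [r.site in surv for r in records],
        }
    )


def sumstats_frame(sites: Sites, results, effects, site_info) -> pd.DataFrame:
    """Summary statistics table; one row per scanned site."""
    eff = {e.site: e for e in effects}
    rows = []
    for r in results:
        e = eff.get(r.site)
        rows.append(
            {
                "CHR": sites.chrom,
                "POS": sites.positions[r.site],
                "ID": f"site{r.site}",
                "REF": BASES[sites.ref[r.site]],
                "ALT": BASES[sites.alt[r.site]],
                "EAF": site_info.est_af[r.site],
                "INFO": site_info.info_score[r.site],
                "N_HIGH": r.n_high,
                "CHI2": r.chi2,
                "P": r.p_value,
                "BETA": e.beta if e else np.nan,
                "SE": e.se if e else np.nan,
                "TESTED": r.tested_flag,
            }
        )
    return pd.DataFrame(rows)


def loci_frame(loci) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": i,
                "chrom": l.chrom,
                "start": l.start,
                "end": l.end,
                "lead_id": l.lead_snp,
                "lead_p": l.lead_p,
                "n_ind": len(l.independent_snps),
                "n_cand": len(l.candidate_snps),
            }
            for i, l in enumerate(loci)
        ]
    )
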