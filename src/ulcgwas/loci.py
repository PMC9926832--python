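"""Post-GWAS locus definition: independent SNPs, leads, candidates, risk loci.

The FUMA-style clumping chain: genome-wide-significant SNPs are thinned
greedily by ascending p-value into *independent significant SNPs*
(pairwise r^2 < 0.6), further into *lead SNPs* (pairwise r^2 < 0.1);
*candidate SNPs* are the independents plus any SNP with p < 0.05 in
r^2 >= 0.6 with an independent SNP. Each lead spans the region of its
nearest candidates and regions closer than a merge distance collapse
iteratively into one genomic risk locus. LD here is the squared Pearson
correlation of the analysis cohort's own dosage vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class RiskLocus:
    chrom: str
    start: int                   # 1-based inclusive span of member candidates
    end: int
    lead_snp: int                # site index of the smallest-p member lead
    lead_p: float
    independent_snps: list[int]
    candidate_snps: list[int]

    @property
    def n_snps(self) -> int:
        return len(self.candidate_snps)


def ld_matrix(dosages: np.ndarray) -> np.ndarray:
    """Pairwise r^2 of dosage vectors; zero-variance columns get r^2 0."""
    D = np.asarray(dosages, dtype=float)
    sd = D.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(D)
    Z[:, ok] = (D[:, ok] - D[:, ok].mean(axis=0)) / sd[ok]
    r = (Z.T @ Z) / D.shape[0]
    r2 = np.clip(r * r, 0.0, 1.0)
    np.fill_diagonal(r2, 1.0)
    return r2


def _greedy_by_p(
    snps: np.ndarray,
    pvals: np.ndarray,
    positions: np.ndarray,
    ld_r2: np.ndarray,
    r2_max: float,
) -> list[int]:
    """Greedy ascending-p selection with a pairwise r^2 ceiling.

    Position is the deterministic tie-break on equal p-values.
    """
    order = sorted(snps, key=lambda j: (pvals[j], positions[j]))
    accepted: list[int] = []
    for j in order:
        r2_row = ld_r2[j, accepted] if accepted else np.array([])
        if np.any(np.isnan(r2_row)):
            raise ValueError("missing LD entry")
        if all(r2_row < r2_max):
            accepted.append(j)
    return accepted


def find_independent(
    pvals: np.ndarray,
    positions: np.ndarray,
    ld_r2: np.ndarray,
    p_thresh: float,
    r2_indep: float = 0.6,
) -> list[int]:
    """Independent significant SNPs: significant and pairwise r^2 < r2_indep."""
    pvals = np.asarray(pvals, dtype=float)
    sig = np.flatnonzero(pvals <= p_thresh)
    return _greedy_by_p(sig, pvals, np.asarray(positions), ld_r2, r2_indep)


def find_leads(
    independents: Sequence[int],
    pvals: np.ndarray,
    positions: np.ndarray,
    ld_r2: np.ndarray,
    r2_lead: float = 0.1,
) -> list[int]:
    """Lead SNPs: the low-LD (r^2 < r2_lead) subset of the independents."""
    return _greedy_by_p(
        np.asarray(list(independents), dtype=np.int64),
        np.asarray(pvals, dtype=float),
        np.asarray(positions),
        ld_r2,
        r2_lead,
    )


def candidate_snps(
    independents: Sequence[int],
    pvals: np.ndarray,
    ld_r2: np.ndarray,
    r2_cand: float = 0.6,
    p_cand: float = 0.05,
) -> list[int]:
    """Independents plus SNPs with p < p_cand linked at r^2 >= r2_cand."""
    ind = list(independents)
    if not ind:
        return []
    pvals = np.asarray(pvals, dtype=float)
    linked = np.flatnonzero(
        (ld_r2[:, ind].max(axis=1) >= r2_cand) & (pvals < p_cand)
    )
    return sorted(set(ind) | set(int(j) for j in linked))


def define_loci(
    leads: Sequence[int],
    candidates: Sequence[int],
    independents: Sequence[int],
    pvals: np.ndarray,
    positions: np.ndarray,
    chrom: str = "1",
    merge_dist: int = 250_000,
) -> list[RiskLocus]:
    """Merge lead regions into genomic risk loci.

    Every candidate joins its nearest lead; a lead's region spans its
    members' positions; regions on the same chromosome closer than
    ``merge_dist`` merge iteratively until a fixed point. The locus lead is
    its smallest-p member lead.
    """
    leads = list(leads)
    if not leads:
        return []
    pvals = np.asarray(pvals, dtype=float)
    positions = np.asarray(positions)
    lead_pos = positions[leads]

    members: dict[int, list[int]] = {li: [li] for li in leads}
    for c in candidates:
        d = np.abs(positions[c] - lead_pos)
        li = leads[int(np.argmin(d))]  # argmin ties resolve to the earlier lead
        if c not in members[li]:
            members[li].append(c)

    regions = []
    for li in leads:
        pos = positions[members[li]]
        regions.append(
            {"start": int(pos.min()), "end": int(pos.max()), "leads": [li],
             "members": set(members[li])}
        )
    regions.sort(key=lambda r: r["start"])

    merged = True
    while merged:
        merged = False
        out = []
        for reg in regions:
            if out and reg["start"] - out[-1]["end"] < merge_dist:
                out[-1]["end"] = max(out[-1]["end"], reg["end"])
                out[-1]["leads"] += reg["leads"]
                out[-1]["members"] |= reg["members"]
                merged = True
            else:
                out.append(reg)
        regions = out

    ind_set = set(independents)
    loci = []
    for reg in regions:
        best = min(reg["leads"], key=lambda j: (pvals[j], positions[j]))
        cand = sorted(reg["members"])
        loci.append(
            RiskLocus(
                chrom=str(chrom),
                start=reg["start"],
                end=reg["end"],
                lead_snp=int(best),
                lead_p=float(pvals[best]),
                independent_snps=sorted(set(cand) & ind_set),
                candidate_snps=cand,
            )
        )
    return loci


def map_genes_positional(
    loci: Sequence[RiskLocus],
    genes: Sequence[tuple[str, int, int, str]],
    positions: np.ndarray,
    max_dist: int = 10_000,
) -> dict[int, set[str]]:
    """Positional gene mapping: genes within max_dist bp of a candidate SNP.

    ``genes`` are BED-like (chrom, start, end, name) with 0-based half-open
    coordinates. Returns, per locus index, the set of mapped gene names.
    """
    for chrom, start, end, _name in genes:
        if end <= start:
            raise ValueError(f"malformed gene interval {chrom}:{start}-{end}")
    positions = np.asarray(positions)
    out: dict[int, set[str]] = {}
    for i, locus in enumerate(loci):
        hits = set()
        snp_pos = positions[locus.candidate_snps]
        for chrom, start, end, name in genes:
            if str(chrom) != locus.chrom:
                continue
            # 1-based inclusive gene span
            lo, hi = start + 1, end
            dist = np.where(
                snp_pos < lo, lo - snp_pos, np.where(snp_pos > hi, snp_pos - hi, 0)
            )
            if (dist <= max_dist).any():
                hits.add(name)
        out[i] = hits
    return out
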