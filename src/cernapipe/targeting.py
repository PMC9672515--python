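"""miRNA target prediction on mRNA 3'UTRs and circRNA spliced sequences.

Canonical seed-match site discovery (8mer, 7mer-m8, 7mer-A1, 6mer, per the
TargetScan site hierarchy), a 0-100 context-style site score, and a
nearest-neighbor RNA/RNA duplex free energy.  A (miRNA, target) pair is
called a targeting relationship when the gene-level score exceeds 50 and
the duplex energy is below -20 kcal/mol, both strict.

The 0-100 score is a surrogate: the commercial pipeline score it stands in
for is unpublished, so the scale here is defined by the seed-class hierarchy
plus AU-flank and 3'-supplementary context bonuses, preserving the decision
structure and the printed threshold semantics.  The energy model is a
Turner-style nearest-neighbor stack sum on the seed-anchored duplex, not a
full Smith-Waterman hybridization alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._seq import complement, is_wc, pairs, validate_rna

__all__ = [
    "SeedSite",
    "SITE_LENGTH",
    "find_seed_sites",
    "score_site",
    "duplex_energy",
    "site_energy",
    "dual_threshold",
    "predict_targets",
    "DUPLEX_INITIATION",
    "LOOP_PENALTY_PER_NT",
]

#: Site length on the target per class.  8mer and 7mer-A1 include the
#: position opposite miRNA nucleotide 1 (the target-side A).
SITE_LENGTH = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}

#: Class precedence, strongest first.
SITE_CLASS_ORDER = ("8mer", "7mer-m8", "7mer-A1", "6mer")


@dataclass(frozen=True)
class SeedSite:
    """One seed-match site on a target, 0-based start, half-open end."""

    target_id: str
    position: int
    site_class: str

    @property
    def length(self) -> int:
        return SITE_LENGTH[self.site_class]

    @property
    def end(self) -> int:
        return self.position + self.length


def _seed_cores(mirna_seq: str) -> tuple[str, str]:
    """(6mer core, m8 complement) for a miRNA.

    The 6mer core is the reverse complement of miRNA nucleotides 2-7,
    written target 5'->3'; prepending the complement of nucleotide 8
    yields the seed+m8 match.
    """
    core6 = ""
    for k in range(7, 1, -1):  # miRNA nt 7..2 -> target 5'->3'
        core6 += complement(mirna_seq[k - 1])
    m8c = complement(mirna_seq[7])
    return core6, m8c


def find_seed_sites(mirna_seq: str, target_seq: str, target_id: str = "") -> list[SeedSite]:
    """Scan a target for canonical seed sites of one miRNA.

    Every occurrence of the 6mer seed match is classified once, at its
    highest class: an m8 match 5'-adjacent on the target upgrades toward
    7mer-m8/8mer, an A opposite miRNA position 1 upgrades toward
    7mer-A1/8mer.  Watson-Crick pairing only.  Sites are returned sorted
    by position.
    """
    validate_rna(mirna_seq, name="miRNA sequence")
    if not 18 <= len(mirna_seq) <= 26:
        raise ValueError(f"miRNA length {len(mirna_seq)} outside 18-26 nt")
    validate_rna(target_seq, name="target sequence")

    core6, m8c = _seed_cores(mirna_seq)
    sites: list[SeedSite] = []
    p = target_seq.find(core6)
    while p != -1:
        m8 = p > 0 and target_seq[p - 1] == m8c
        a1 = p + 6 < len(target_seq) and target_seq[p + 6] == "A"
        if m8 and a1:
            sites.append(SeedSite(target_id, p - 1, "8mer"))
        elif m8:
            sites.append(SeedSite(target_id, p - 1, "7mer-m8"))
        elif a1:
            sites.append(SeedSite(target_id, p, "7mer-A1"))
        else:
            sites.append(SeedSite(target_id, p, "6mer"))
        p = target_seq.find(core6, p + 1)
    return sites


def _core_start(site: SeedSite) -> int:
    """Target index of the 6mer-core start (skips the m8 base if present)."""
    if site.site_class in ("8mer", "7mer-m8"):
        return site.position + 1
    return site.position


def _three_prime_run(site: SeedSite, mirna_seq: str, target_seq: str) -> int:
    """Longest consecutive Watson-Crick run between miRNA nt 13-17 and the
    target region opposite them (5' of the seed match on the target)."""
    q = _core_start(site)
    best = run = 0
    for k in range(13, 18):
        if k > len(mirna_seq):
            break
        t = q + 7 - k
        if 0 <= t < len(target_seq) and is_wc(mirna_seq[k - 1], target_seq[t]):
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


_BASE_SCORE = {"8mer": 75.0, "7mer-m8": 60.0, "7mer-A1": 55.0, "6mer": 40.0}


def score_site(site: SeedSite, mirna_seq: str, target_seq: str) -> float:
    """Context-style 0-100 site score.

    base(class) + 15 * AU fraction of the 30 nt flanking the site
    (truncated at sequence ends) + 2 * longest consecutive Watson-Crick
    run between miRNA positions 13-17 and the opposite target region
    (capped at 10); total capped at 100.
    """
    flank = (
        target_seq[max(0, site.position - 15) : site.position]
        + target_seq[site.end : site.end + 15]
    )
    au = sum(1 for ch in flank if ch in "AU") / len(flank) if flank else 0.0
    threep = min(10.0, 2.0 * _three_prime_run(site, mirna_seq, target_seq))
    return min(100.0, _BASE_SCORE[site.site_class] + 15.0 * au + threep)


# Turner-2004 Watson-Crick RNA/RNA nearest-neighbor stack free energies
# (kcal/mol), keyed by the top-strand (miRNA, 5'->3') dinucleotide; the
# bottom strand is the Watson-Crick complement.  The 10 published unique
# values expanded to all 16 keys by the strand-exchange symmetry
# dG(5'XY3'/3'X'Y'5') = dG(5'Y'X'3'/3'YX5').
STACK_WC = {
    "AA": -0.93, "UU": -0.93,
    "AU": -1.10,
    "UA": -1.33,
    "CU": -2.08, "AG": -2.08,
    "CA": -2.11, "UG": -2.11,
    "GU": -2.24, "AC": -2.24,
    "GA": -2.35, "UC": -2.35,
    "CG": -2.36,
    "GG": -3.26, "CC": -3.26,
    "GC": -3.42,
}

#: Flat stack term applied when either pair of a stack is a G:U wobble.
STACK_WOBBLE = -1.2

DUPLEX_INITIATION = 4.09
LOOP_PENALTY_PER_NT = 1.0
MAX_PAIRED_POSITION = 17


def duplex_energy(mirna_seq: str, target_site_region: str) -> float:
    """Nearest-neighbor free energy (kcal/mol) of a seed-anchored duplex.

    The target region is the window opposite miRNA positions 1..17,
    written 5'->3' on the target, so its 3'-terminal base sits opposite
    miRNA position 1 (pad with N on the 3' side if the site runs off the
    target end).  Position k of the miRNA pairs the region base
    len(region)-k; Watson-Crick and G:U pairs count, N never pairs.
    Energy = +4.09 initiation + stack terms over consecutive paired
    positions + 1.0 per unpaired nucleotide interior to the paired span.
    """
    L = len(target_site_region)
    paired = []
    for k in range(1, min(MAX_PAIRED_POSITION, len(mirna_seq), L) + 1):
        t = target_site_region[L - k]
        if t != "N" and pairs(mirna_seq[k - 1], t):
            paired.append(k)
    if not paired:
        return DUPLEX_INITIATION

    def _stack(k: int) -> float:
        # stack of pairs at miRNA positions k and k+1
        m1, m2 = mirna_seq[k - 1], mirna_seq[k]
        t1, t2 = target_site_region[L - k], target_site_region[L - k - 1]
        if is_wc(m1, t1) and is_wc(m2, t2):
            return STACK_WC[m1 + m2]
        return STACK_WOBBLE

    dg = DUPLEX_INITIATION
    pset = set(paired)
    for k in range(paired[0], paired[-1]):
        if k in pset and k + 1 in pset:
            dg += _stack(k)
        elif k + 1 not in pset:
            dg += LOOP_PENALTY_PER_NT
    return dg


def site_energy(site: SeedSite, mirna_seq: str, target_seq: str) -> float:
    """Duplex energy of one discovered site, extracting the opposite window."""
    q = _core_start(site)
    lo, hi = q - 10, q + 7
    region = target_seq[max(0, lo) : min(len(target_seq), hi)]
    if hi > len(target_seq):  # site at the target 3' end: pad the A1 slot
        region += "N" * (hi - len(target_seq))
    return duplex_energy(mirna_seq, region)


def dual_threshold(
    score: float,
    energy: float,
    score_threshold: float = 50.0,
    energy_threshold: float = -20.0,
) -> bool:
    """The targeting call: score > 50 and energy < -20, both strict."""
    return score > score_threshold and energy < energy_threshold


def predict_targets(
    mirnas: dict[str, str],
    targets: dict[str, str],
    layer: str,
    score_threshold: float = 50.0,
    energy_threshold: float = -20.0,
) -> pd.DataFrame:
    """Score all (miRNA, target) pairs with at least one seed site.

    Gene-level score is the max over sites, energy the min over sites;
    ``passes`` requires score > score_threshold and energy < energy_threshold
    (both strict).  Returns a DataFrame sorted by (mirna_id, target_id) with
    the best-scoring site's class and position.
    """
    rows = []
    for mid in sorted(mirnas):
        mseq = mirnas[mid]
        for tid in sorted(targets):
            tseq = targets[tid]
            sites = find_seed_sites(mseq, tseq, target_id=tid)
            if not sites:
                continue
            scored = [(score_site(s, mseq, tseq), s) for s in sites]
            best_score, best_site = max(scored, key=lambda t: (t[0], -t[1].position))
            energy = min(site_energy(s, mseq, tseq) for s in sites)
            rows.append(
                {
                    "mirna_id": mid,
                    "target_id": tid,
                    "layer": layer,
                    "site_class": best_site.site_class,
                    "position": best_site.position,
                    "n_sites": len(sites),
                    "score": round(best_score, 6),
                    "energy": round(energy, 6),
                    "passes": dual_threshold(best_score, energy, score_threshold, energy_threshold),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id", "target_id", "layer", "site_class", "position",
            "n_sites", "score", "energy", "passes",
        ],
    )
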