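"""Independent brute-force oracles used to validate the implementation.

These deliberately share no code with the package: digestion enumerates all
substrings and checks boundary/internal cut-site conditions directly; ORF
finding enumerates every ATG..stop span; search scans with a naive loop.
"""

from __future__ import annotations

_STOPS = {"TAA", "TAG", "TGA"}


def brute_force_cut_sites(protein: str, residues: str, terminus: str, blocked: str) -> set[int]:
    sites = set()
    for i in range(1, len(protein)):
        if terminus == "C":
            if protein[i - 1] in residues and protein[i] not in blocked:
                sites.add(i)
        else:
            if protein[i] in residues:
                sites.add(i)
    return sites


def brute_force_digest(
    protein: str, residues: str, terminus: str, blocked: str, max_mc: int
) -> set[tuple[str, int, int, int]]:
    """All (sequence, start, end, mc) whose ends are cut sites or termini and
    whose internal cut-site count is <= max_mc."""
    sites = brute_force_cut_sites(protein, residues, terminus, blocked)
    bounds = sites | {0, len(protein)}
    out = set()
    for a in range(len(protein)):
        for b in range(a + 1, len(protein) + 1):
            if a not in bounds or b not in bounds:
                continue
            internal = sum(1 for s in sites if a < s < b)
            if internal <= max_mc:
                out.add((protein[a:b], a + 1, b, internal))
    return out


def brute_force_orf(cdna: str, min_codons: int):
    """(start_nt, end_nt, protein, complete) per the documented selection rule.

    All ATG..stop spans in the three forward frames are enumerated; the
    longest complete ORF encoding >= min_codons residues wins, ties broken
    by 5'-most start.  Failing that, the longest ATG-to-end open span is
    returned incomplete; failing that, the longest complete ORF below the
    threshold.  No ATG -> None.
    """
    from Bio.Seq import Seq

    n = len(cdna)
    complete, incomplete = [], []
    for i in range(n - 2):
        if cdna[i : i + 3] != "ATG":
            continue
        stop = None
        for j in range(i + 3, n - 2, 3):
            if cdna[j : j + 3] in _STOPS:
                stop = j
                break
        if stop is not None:
            prot = str(Seq(cdna[i:stop]).translate())
            complete.append((i + 1, stop + 3, prot, True))
        else:
            span = (n - i) // 3 * 3
            if span >= 3:
                prot = str(Seq(cdna[i : i + span]).translate())
                incomplete.append((i + 1, i + span, prot, False))
    # nested ATGs sharing a stop: keep all; selection handles length ties
    qualified = [o for o in complete if len(o[2]) >= min_codons]
    pool = qualified or incomplete or complete
    if not pool:
        return None
    return min(pool, key=lambda o: (-len(o[2]), o[0]))


def brute_force_search(query: str, proteome: dict[str, str], max_mismatches: int):
    """All (transcript_id, start_1based, mismatches) windows within tolerance."""
    hits = set()
    q = len(query)
    for tid, seq in proteome.items():
        for i in range(len(seq) - q + 1):
            mism = sum(1 for a, b in zip(query, seq[i : i + q]) if a != b)
            if mism <= max_mismatches:
                hits.add((tid, i + 1, mism))
    return hits


#: (cleave residues, terminus, blocking residues) per protease, stated
#: independently of the package's rule table.
ORACLE_RULES = {
    "trypsin": ("KR", "C", "P"),
    "lysc": ("K", "C", ""),
    "lysn": ("K", "N", ""),
    "aspn": ("D", "N", ""),
    "chymotrypsin": ("FYW", "C", "P"),
    "gluc": ("E", "C", ""),
}
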