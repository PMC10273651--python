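"""Plant miRNA target-site scoring on circular and linear transcripts.

Scoring follows the plant penalty scheme: each mismatch costs 1, each G:U
wobble 0.5, each bulged position 1; penalties are doubled at miRNA positions
2-13 (counting from the miRNA 5' end; position 1 is exempt). At most one
bulged position per site is searched (window lengths of miRNA length +/- 1).
Sites with total penalty <= cutoff (default 4.0) are reported; overlapping
sites of the same miRNA collapse to the best-scoring (leftmost on ties).

Circular transcripts are scanned junction-aware: the sequence is extended by
its own prefix so windows crossing the back-splice seam are visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GeneModel, Genome, extract_sequence, reverse_complement

MAX_BULGE = 1

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# penalty lookup indexed by [revcomp(miRNA) base, target base]:
# equality = Watson-Crick pair; (C,T) and (A,G) = G:U wobble; anything
# involving N, and every other combination, is a mismatch.
_PEN = np.ones((5, 5))
for _i in range(4):
    _PEN[_i, _i] = 0.0
_PEN[_CODE["C"], _CODE["T"]] = 0.5  # miRNA G : target U
_PEN[_CODE["A"], _CODE["G"]] = 0.5  # miRNA U : target G
_PEN[4, :] = 1.0
_PEN[:, 4] = 1.0


@dataclass(frozen=True)
class MiRNA:
    name: str
    sequence: str  # DNA alphabet internally

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if not 19 <= len(seq) <= 24:
            raise ValueError(f"{self.name}: miRNA length {len(seq)} outside 19-24")
        if set(seq) - set("ACGT"):
            raise ValueError(f"{self.name}: invalid alphabet")


@dataclass
class TargetSite:
    transcript_id: str
    mirna: str
    start: int  # offset on the (possibly circular) transcript
    window_length: int
    penalty_score: float
    pairing: str
    spans_junction: bool


def _codes(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)
    for b, c in _CODE.items():
        table[ord(b)] = c
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _position_multipliers(n: int) -> np.ndarray:
    """Doubling mask over the reversed-miRNA frame (index j = position n-j)."""
    pos = n - np.arange(n)  # 1-based miRNA position at reversed index j
    return np.where((pos >= 2) & (pos <= 13), 2.0, 1.0)


def _bulge_penalty(position: int) -> float:
    p = max(1, position)
    return 2.0 if 2 <= p <= 13 else 1.0


def score_mirna_site(mirna: str | MiRNA, window: str) -> float:
    """Penalty of aligning a miRNA against one candidate target window.

    The window is the target strand read 5'->3'; a reported site is the
    reverse complement of the miRNA up to mismatches/wobbles/one bulge.
    Window length must be within +/-1 of the miRNA length.
    """
    m = mirna.sequence if isinstance(mirna, MiRNA) else mirna.upper().replace("U", "T")
    n = len(m)
    w = len(window)
    if w < n - MAX_BULGE:
        raise ValueError(f"window of {w} nt shorter than miRNA - {MAX_BULGE}")
    if w > n + MAX_BULGE:
        raise ValueError(f"window of {w} nt longer than miRNA + {MAX_BULGE}")
    mrc = _codes(reverse_complement(m))
    t = _codes(window.upper().replace("U", "T"))
    mult = _position_multipliers(n)

    def pen(j: int, tc: int) -> float:
        return float(_PEN[mrc[j], tc]) * mult[j]

    if w == n:
        return float(sum(pen(j, t[j]) for j in range(n)))
    if w == n + 1:  # one bulged target base
        best = np.inf
        for k in range(n + 1):
            total = sum(pen(j, t[j]) for j in range(k))
            total += _bulge_penalty(n - k)
            total += sum(pen(j, t[j + 1]) for j in range(k, n))
            best = min(best, total)
        return float(best)
    # w == n - 1: one unpaired miRNA base
    best = np.inf
    for k in range(n):
        total = sum(pen(j, t[j]) for j in range(k))
        total += _bulge_penalty(n - k)
        total += sum(pen(j, t[j - 1]) for j in range(k + 1, n))
        best = min(best, total)
    return float(best)


def pairing_string(mirna: str | MiRNA, window: str) -> str:
    """Ungapped pairing diagram, miRNA 3'->5' over the window ('|' pair,
    'o' wobble, '.' mismatch); bulged windows are marked with '~'."""
    m = mirna.sequence if isinstance(mirna, MiRNA) else mirna.upper().replace("U", "T")
    if len(window) != len(m):
        return "~" * len(window)
    mrc = _codes(reverse_complement(m))
    t = _codes(window)
    out = []
    for j in range(len(m)):
        p = _PEN[mrc[j], t[j]]
        out.append("|" if p == 0 else ("o" if p == 0.5 else "."))
    return "".join(out)


# ---------------------------------------------------------------------------
# vectorized scan


def _scan_penalties(mrc: np.ndarray, mult: np.ndarray, t: np.ndarray):
    """Best penalties for every start over the three window forms.

    Returns (best, form) arrays over starts 0..len(t)-n; form is the window
    length delta (-1, 0, +1).
    """
    n = mrc.size
    S = t.size
    n_starts = S - n + 1
    if n_starts <= 0:
        return np.empty(0), np.empty(0, dtype=int)

    # A[j, s]: pair j against t[s+j]; B: t[s+j+1]; C: t[s+j-1]
    A = np.empty((n, n_starts))
    for j in range(n):
        A[j] = _PEN[mrc[j], t[j : j + n_starts]] * mult[j]
    nogap = A.sum(axis=0)

    # one bulged target base (window n+1): starts with s+n <= S-1
    nb = n_starts - 1
    tb = np.full(n_starts, np.inf)
    if nb > 0:
        B = np.empty((n, nb))
        for j in range(n):
            B[j] = _PEN[mrc[j], t[j + 1 : j + 1 + nb]] * mult[j]
        cumA = np.vstack([np.zeros(nb), np.cumsum(A[:, :nb], axis=0)])
        cumB = np.vstack([np.zeros(nb), np.cumsum(B, axis=0)])
        suffB = cumB[n] - cumB
        cand = np.full((n + 1, nb), np.inf)
        for k in range(n + 1):
            cand[k] = cumA[k] + _bulge_penalty(n - k) + suffB[k]
        tb[:nb] = cand.min(axis=0)

    # one unpaired miRNA base (window n-1): all starts valid, plus one extra
    mb = np.full(n_starts, np.inf)
    C = np.empty((n, n_starts))
    C[0] = np.inf  # j=0 in the shifted frame would read t[s-1]
    for j in range(1, n):
        C[j] = _PEN[mrc[j], t[j - 1 : j - 1 + n_starts]] * mult[j]
    cumA_full = np.vstack([np.zeros(n_starts), np.cumsum(A, axis=0)])
    Cz = np.where(np.isfinite(C), C, 0.0)
    cumC = np.vstack([np.zeros(n_starts), np.cumsum(Cz, axis=0)])
    cand = np.full((n, n_starts), np.inf)
    for k in range(n):
        suff = cumC[n] - cumC[k + 1]
        cand[k] = cumA_full[k] + _bulge_penalty(n - k) + suff
    mb = cand.min(axis=0)

    stack = np.vstack([mb, nogap, tb])
    form = stack.argmin(axis=0) - 1  # -1, 0, +1
    best = stack.min(axis=0)
    return best, form


def scan_transcript(
    mirnas: dict[str, str] | list[MiRNA],
    transcript_id: str,
    sequence: str,
    circular: bool,
    cutoff: float = 4.0,
) -> list[TargetSite]:
    """All accepted miRNA sites on one transcript.

    ``circular`` extends the sequence by its first (miRNA length + MAX_BULGE
    - 1) nt so windows crossing the back-splice seam are scanned;
    ``spans_junction`` is set for those. Overlapping sites of one miRNA are
    collapsed to the best-scoring (leftmost wins ties).
    """
    if not sequence:
        raise ValueError("empty transcript sequence")
    if isinstance(mirnas, dict):
        mirnas = [MiRNA(k, v) for k, v in mirnas.items()]
    L = len(sequence)
    seq = sequence.upper().replace("U", "T")
    sites: list[TargetSite] = []
    for mi in sorted(mirnas, key=lambda m: m.name):
        n = len(mi.sequence)
        ext = seq + seq[: n + MAX_BULGE - 1] if circular else seq
        if L < n - MAX_BULGE:
            continue
        t = _codes(ext)
        mrc = _codes(reverse_complement(mi.sequence))
        mult = _position_multipliers(n)
        best, form = _scan_penalties(mrc, mult, t)
        n_starts = min(best.size, L) if circular else best.size
        cand = [
            (float(best[s]), s, int(form[s]))
            for s in range(n_starts)
            if best[s] <= cutoff
        ]
        cand.sort(key=lambda x: (x[0], x[1]))
        covered: set[int] = set()
        for pen_val, s, f in cand:
            wlen = n + f
            positions = {(s + i) % L if circular else s + i for i in range(wlen)}
            if positions & covered:
                continue
            covered |= positions
            window = ext[s : s + wlen]
            sites.append(
                TargetSite(
                    transcript_id=transcript_id,
                    mirna=mi.name,
                    start=s,
                    window_length=wlen,
                    penalty_score=pen_val,
                    pairing=pairing_string(mi, window),
                    spans_junction=bool(circular and s + wlen > L),
                )
            )
    sites.sort(key=lambda x: (x.mirna, x.start))
    return sites


# ---------------------------------------------------------------------------
# circular mature sequence and the ceRNA network


def circular_sequence(
    exon_indices: list[int], gene: GeneModel, genome: Genome
) -> str:
    """Mature circRNA sequence: circularized exons joined in transcription
    order (minus-strand genes come out reverse-complemented per exon)."""
    if not exon_indices:
        raise ValueError("non-exonic circRNA has no mature sequence")
    parts = [
        extract_sequence(genome, gene.exons[rank - 1]) for rank in sorted(exon_indices)
    ]
    return "".join(parts)


def build_cerna_network(
    circ_sites: list[TargetSite], mrna_sites: list[TargetSite]
) -> dict:
    """Edge table (circRNA->miRNA, miRNA->mRNA) and degree summaries."""
    edges: list[tuple[str, str, str, float, bool]] = []
    seen = set()
    for s in circ_sites:
        k = (s.transcript_id, s.mirna)
        if k not in seen:
            seen.add(k)
            edges.append((s.transcript_id, s.mirna, "circ-miRNA", s.penalty_score, s.spans_junction))
    for s in mrna_sites:
        k = (s.mirna, s.transcript_id)
        if k not in seen:
            seen.add(k)
            edges.append((s.mirna, s.transcript_id, "miRNA-mRNA", s.penalty_score, False))
    df = pd.DataFrame(
        edges, columns=["source", "target", "type", "penalty", "spans_junction"]
    )
    circ_edges = df[df["type"] == "circ-miRNA"]
    mirnas_per_circ = circ_edges.groupby("source").size()
    circs_per_mirna = circ_edges.groupby("target").size()
    return {
        "edges": df,
        "mirnas_per_circ_hist": mirnas_per_circ.value_counts().sort_index().to_dict(),
        "circs_per_mirna_hist": circs_per_mirna.value_counts().sort_index().to_dict(),
        "n_sponge_circs": int(circ_edges["source"].nunique()),
        "n_mirnas": int(circ_edges["target"].nunique()),
    }
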