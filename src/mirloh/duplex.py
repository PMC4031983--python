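"""miRNA:target pairing utilities: Watson-Crick + G:U wobble duplexes.

Implements the two pairing criteria used when defining and mutating miRNA
recognition elements (MREs):

* :func:`best_ungapped_duplex` scores every ungapped antiparallel offset of a
  miRNA against a candidate site, counting Watson-Crick (A:U, C:G) and G:U
  wobble pairs; mutant MREs are designed by breaking exactly these pairs.
* :func:`is_canonical_seed_site` asks whether a site pairs by Watson-Crick
  only with miRNA positions 2-7 (6-mer seed) or 2-8 (7-mer seed) from the
  miRNA 5' end; wobbles do not count for canonical seeds.

T and U are equivalent throughout (printed oligos are DNA, mature miRNAs are
RNA). No thermodynamic scoring is attempted: the score is the pair count.
"""

from __future__ import annotations

from dataclasses import dataclass

VALID = set("ACGUT")
WC_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
GU_PAIRS = {("G", "U"), ("U", "G")}

#: 5' cloning overhangs seen on printed MRE oligos.
CLONING_OVERHANGS = ("TCGA", "GGCC")


def _norm(seq: str, name: str) -> str:
    s = seq.upper().replace("T", "U")
    for i, c in enumerate(s):
        if c not in "ACGU":
            raise ValueError(
                f"{name}: invalid character {seq[i]!r} at position {i + 1}"
            )
    if not s:
        raise ValueError(f"{name}: sequence is empty")
    return s


def trim_cloning_overhang(seq: str) -> str:
    """Strip a known 5' cloning overhang (TCGA/GGCC) if present."""
    up = seq.upper()
    for ov in CLONING_OVERHANGS:
        if up.startswith(ov):
            return seq[len(ov):]
    return seq


def reverse_complement(seq: str, as_rna: bool = True) -> str:
    s = _norm(seq, "seq")
    comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
    rc = "".join(comp[c] for c in reversed(s))
    return rc if as_rna else rc.replace("U", "T")


def _pair_type(m: str, t: str) -> str | None:
    if (m, t) in WC_PAIRS:
        return "WC"
    if (m, t) in GU_PAIRS:
        return "GU"
    return None


@dataclass(frozen=True)
class DuplexAlignment:
    """An ungapped antiparallel miRNA:site alignment.

    ``pairs`` lists ``(mirna_pos, target_pos, type)`` with 1-based positions
    along each input sequence (both 5'->3') and type ``"WC"`` or ``"GU"``.
    ``seed_paired`` is true when miRNA positions 2-7 are all Watson-Crick
    paired in this alignment.
    """

    offset: int
    pairs: tuple[tuple[int, int, str], ...]
    seed_paired: bool

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def best_ungapped_duplex(mirna: str, site: str, trim_overhangs: bool = False) -> DuplexAlignment:
    """Best ungapped antiparallel duplex of a miRNA against a target site.

    Both sequences are given 5'->3'. All relative offsets (including partial
    overlaps) are scanned; the alignment maximizing the number of allowed
    pairs (WC + G:U) wins, ties broken by the smallest offset. Offset ``k``
    aligns miRNA position 1 opposite reversed-site index ``k`` (0-based), i.e.
    larger offsets slide the miRNA toward the site's 5' end.
    """
    if trim_overhangs:
        site = trim_cloning_overhang(site)
    m = _norm(mirna, "mirna")
    s = _norm(site, "site")
    s_rev = s[::-1]  # antiparallel: walk the site 3'->5'
    n_m, n_s = len(m), len(s)

    best: DuplexAlignment | None = None
    for offset in range(-(n_m - 1), n_s):
        pairs = []
        for i in range(n_m):
            j = offset + i
            if j < 0 or j >= n_s:
                continue
            ptype = _pair_type(m[i], s_rev[j])
            if ptype is not None:
                # target position in the original 5'->3' site coordinates
                pairs.append((i + 1, n_s - j, ptype))
        seed_ok = all(
            any(p[0] == q and p[2] == "WC" for p in pairs) for q in range(2, 8)
        )
        cand = DuplexAlignment(offset=offset, pairs=tuple(pairs), seed_paired=seed_ok)
        if best is None or cand.n_pairs > best.n_pairs:
            best = cand
    assert best is not None
    return best


@dataclass(frozen=True)
class SeedMatch:
    """Outcome of the canonical-seed scan: which seed lengths match where."""

    is_site: bool
    seed6_positions: tuple[int, ...]  # 1-based site positions of 6-mer matches
    seed7_positions: tuple[int, ...]

    @property
    def kinds(self) -> tuple[str, ...]:
        kinds = []
        if self.seed6_positions:
            kinds.append("6mer")
        if self.seed7_positions:
            kinds.append("7mer")
        return tuple(kinds)


def is_canonical_seed_site(mirna: str, site_3utr_context: str) -> SeedMatch:
    """Scan a 3'UTR context for canonical seed matches of a miRNA.

    A canonical site pairs by Watson-Crick only (no wobble) with miRNA
    positions 2-7 (6-mer) or 2-8 (7-mer); i.e. the site contains the reverse
    complement of that seed stretch.
    """
    m = _norm(mirna, "mirna")
    if len(m) < 8:
        raise ValueError(f"miRNA must be at least 8 nt, got {len(m)}")
    ctx = _norm(site_3utr_context, "site_3utr_context")

    def matches(seed: str) -> tuple[int, ...]:
        target = reverse_complement(seed)
        hits = []
        for i in range(len(ctx) - len(target) + 1):
            if ctx[i : i + len(target)] == target:
                hits.append(i + 1)
        return tuple(hits)

    six = matches(m[1:7])
    seven = matches(m[1:8])
    return SeedMatch(is_site=bool(six or seven), seed6_positions=six, seed7_positions=seven)
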