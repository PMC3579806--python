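"""Seed-match plus hybridization-energy miRNA target prediction.

A site is called when (1) the target window pairs the miRNA seed
(mature positions 2-8 by default) antiparallel with only Watson-Crick
pairs, optionally allowing a budget of G:U wobbles, and (2) the
miRNA:mRNA duplex anchored on that seed helix has a minimum free energy
below a strict threshold (-20 kcal/mol by default).

The duplex model is intermolecular-only (no hairpins within either
strand): stacked base pairs scored by a nearest-neighbor table, bulges
and internal loops by an affine penalty, plus one initiation term.
``duplex_mfe`` optimizes freely over all antiparallel non-crossing
pairings; ``predict_targets`` scores each seed match with the seed helix
held fixed and optimal 5'/3' extensions, so every accepted site's
pairing trace covers the full seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

RNA_BASES = set("ACGU")
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}
WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "U"), ("U", "G")}
ALLOWED_PAIRS = WC_PAIRS | GU_PAIRS

DEFAULT_SEED_WINDOW = (2, 8)
DEFAULT_ENERGY_THRESHOLD = -20.0
DEFAULT_FLANK = 30  # target bases considered on each side of a seed match


def to_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U; validate the alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_BASES - {"N"}
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in sequence")
    return s


def reverse_complement_rna(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(to_rna(seq)))


@dataclass(frozen=True)
class EnergyParameters:
    """Nearest-neighbor duplex energy model (kcal/mol)."""

    stack_energies: dict[tuple[str, str], float]
    duplex_init: float
    loop_open: float
    loop_per_nt: float
    max_loop: int = 10

    def __post_init__(self) -> None:
        for (p1, p2), e in self.stack_energies.items():
            wc = tuple(p1) in WC_PAIRS and tuple(p2) in WC_PAIRS
            if wc and e > 0:
                raise ValueError(f"Watson-Crick stack {p1}/{p2} must be <= 0")
        if self.loop_open < 0 or self.loop_per_nt < 0:
            raise ValueError("loop penalties must be >= 0")


def load_energy_parameters(path: str | Path | None = None) -> EnergyParameters:
    """Load the shipped (or a user-supplied) tab-delimited parameter file."""
    if path is None:
        text = (resources.files("mirfsh") / "data" / "stack_energies.tsv").read_text()
    else:
        text = Path(path).read_text()
    stacks: dict[tuple[str, str], float] = {}
    params: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kind, *rest = line.split("\t")
        if kind == "param":
            params[rest[0]] = float(rest[1])
        elif kind == "stack":
            stacks[(rest[0], rest[1])] = float(rest[2])
        else:
            raise ValueError(f"unknown row type {kind!r} in energy file")
    return EnergyParameters(
        stack_energies=stacks,
        duplex_init=params["duplex_init"],
        loop_open=params["loop_open"],
        loop_per_nt=params["loop_per_nt"],
    )


@dataclass
class DuplexResult:
    """Optimal intermolecular duplex; ``mfe`` is None when no duplex
    (at least two base pairs) can form."""

    mfe: float | None
    # (strand1 position, strand2 position, "WC" | "GU"), 1-based, strand1 ascending
    pairing_trace: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def has_duplex(self) -> bool:
        return self.mfe is not None


def _pair_class(b1: str, b2: str) -> str | None:
    if (b1, b2) in WC_PAIRS:
        return "WC"
    if (b1, b2) in GU_PAIRS:
        return "GU"
    return None


def _stack(params: EnergyParameters, p1: tuple[str, str], p2: tuple[str, str]) -> float:
    return params.stack_energies[("".join(p1), "".join(p2))]


def _loop_cost(params: EnergyParameters, l1: int, l2: int) -> float:
    return params.loop_open + params.loop_per_nt * (l1 + l2)


def duplex_mfe(
    seq1: str, seq2: str, params: EnergyParameters | None = None,
) -> DuplexResult:
    """Minimum free energy over all antiparallel intermolecular pairings.

    ``seq1`` and ``seq2`` are both 5'->3'. A duplex needs at least two
    base pairs (one stack or loop-closed pair step); otherwise the
    no-duplex sentinel is returned. Loops are capped at ``params.max_loop``
    unpaired bases per strand.
    """
    if params is None:
        params = load_energy_parameters()
    s1 = to_rna(seq1)
    s2 = to_rna(seq2)
    if not s1 or not s2:
        return DuplexResult(mfe=None)
    m, n = len(s1), len(s2)
    r = s2[::-1]  # index k: target position n - k (1-based)
    L = params.max_loop

    pairable = [[_pair_class(s1[i], r[k]) is not None for k in range(n)] for i in range(m)]
    INF = math.inf
    # single[i][k]: chain of exactly one pair; multi[i][k]: >= 2 pairs, ending (i, k)
    single = [[INF] * n for _ in range(m)]
    multi = [[INF] * n for _ in range(m)]
    back: dict[tuple[int, int], tuple[int, int]] = {}
    for i in range(m):
        for k in range(n):
            if not pairable[i][k]:
                continue
            single[i][k] = params.duplex_init
            best, arg = INF, None
            p_now = (s1[i], r[k])
            for ip in range(max(0, i - 1 - L), i):
                l1 = i - ip - 1
                for kp in range(max(0, k - 1 - L), k):
                    if not pairable[ip][kp]:
                        continue
                    l2 = k - kp - 1
                    prev = min(single[ip][kp], multi[ip][kp])
                    if prev == INF:
                        continue
                    if l1 == 0 and l2 == 0:
                        cost = _stack(params, (s1[ip], r[kp]), p_now)
                    else:
                        cost = _loop_cost(params, l1, l2)
                    cand = prev + cost
                    if cand < best:
                        best, arg = cand, (ip, kp)
            if arg is not None:
                multi[i][k] = best
                back[(i, k)] = arg

    mfe, end = INF, None
    for i in range(m):
        for k in range(n):
            if multi[i][k] < mfe:
                mfe, end = multi[i][k], (i, k)
    if end is None:
        return DuplexResult(mfe=None)

    # walk back: chain is built left-to-right; prefer multi predecessor when
    # it produced the recorded value, else stop at the single-pair start
    trace: list[tuple[int, int, str]] = []
    i, k = end
    while True:
        trace.append((i + 1, n - k, _pair_class(s1[i], r[k])))
        if (i, k) not in back:
            break
        ip, kp = back[(i, k)]
        l1, l2 = i - ip - 1, k - kp - 1
        cost = (
            _stack(params, (s1[ip], r[kp]), (s1[i], r[k]))
            if l1 == 0 and l2 == 0
            else _loop_cost(params, l1, l2)
        )
        target = (multi[i][k] if (i, k) in back else single[i][k]) - cost
        if (ip, kp) in back and abs(multi[ip][kp] - target) < 1e-9:
            i, k = ip, kp
        else:
            trace.append((ip + 1, n - kp, _pair_class(s1[ip], r[kp])))
            break
    trace.reverse()
    return DuplexResult(mfe=mfe, pairing_trace=trace)


def extract_seed(sequence: str, window: tuple[int, int] = DEFAULT_SEED_WINDOW) -> str:
    """Seed subsequence at 1-based inclusive ``window`` of the mature miRNA."""
    start, end = window
    if start < 1 or end < start:
        raise ValueError(f"bad seed window {window}")
    s = to_rna(sequence)
    if len(s) < end:
        raise ValueError(
            f"sequence of length {len(s)} too short for seed window {window}"
        )
    return s[start - 1 : end]


@dataclass(frozen=True)
class SeedMatch:
    start: int  # 1-based inclusive on the UTR
    end: int
    seed_class: str  # "all-WC" | "contains-GU"
    n_gu: int


def seed_match_scan(
    seed: str,
    utr: str,
    allow_gu: bool = True,
    max_gu: int = 1,
) -> list[SeedMatch]:
    """All UTR windows whose antiparallel pairing with the seed uses only
    allowed pair classes. Overlapping hits are all reported."""
    if not seed:
        raise ValueError("empty seed")
    s = to_rna(seed)
    u = to_rna(utr)
    L = len(s)
    hits: list[SeedMatch] = []
    for start in range(len(u) - L + 1):
        window = u[start : start + L]
        n_gu = 0
        ok = True
        for i in range(L):
            cls = _pair_class(s[i], window[L - 1 - i])
            if cls is None:
                ok = False
                break
            if cls == "GU":
                n_gu += 1
        if not ok or (n_gu > 0 and not allow_gu) or n_gu > max_gu:
            continue
        hits.append(
            SeedMatch(
                start=start + 1,
                end=start + L,
                seed_class="all-WC" if n_gu == 0 else "contains-GU",
                n_gu=n_gu,
            )
        )
    return hits


def _best_extension(
    s1: str, s2: str, anchor: tuple[str, str], params: EnergyParameters
) -> float:
    """Lowest additional energy (<= 0) of a pairing chain extending away from
    an anchored pair. ``s1``/``s2`` both run outward from the anchor."""
    m, n = len(s1), len(s2)
    if m == 0 or n == 0:
        return 0.0
    L = params.max_loop
    INF = math.inf
    E = [[INF] * n for _ in range(m)]
    best = 0.0
    for i in range(m):
        for k in range(n):
            cls = _pair_class(s1[i], s2[k])
            if cls is None:
                continue
            p_now = (s1[i], s2[k])
            # link from the anchor
            if i == 0 and k == 0:
                e = _stack(params, anchor, p_now)
            elif i <= L and k <= L:
                e = _loop_cost(params, i, k)
            else:
                e = INF
            for ip in range(max(0, i - 1 - L), i):
                for kp in range(max(0, k - 1 - L), k):
                    if E[ip][kp] == INF:
                        continue
                    l1, l2 = i - ip - 1, k - kp - 1
                    if l1 == 0 and l2 == 0:
                        cost = _stack(params, (s1[ip], s2[kp]), p_now)
                    else:
                        cost = _loop_cost(params, l1, l2)
                    e = min(e, E[ip][kp] + cost)
            E[i][k] = e
            best = min(best, e)
    return best


def site_energy(
    mature: str,
    utr: str,
    match_start: int,
    params: EnergyParameters | None = None,
    seed_window: tuple[int, int] = DEFAULT_SEED_WINDOW,
    flank: int = DEFAULT_FLANK,
) -> float:
    """Duplex MFE anchored on the seed helix at a given seed match.

    The seed (mature positions ``seed_window``) is paired against the UTR
    window starting at 1-based ``match_start``; the remainder of the mature
    pairs optimally within ``flank`` UTR bases on either side.
    """
    if params is None:
        params = load_energy_parameters()
    mat = to_rna(mature)
    u = to_rna(utr)
    w0, w1 = seed_window
    L = w1 - w0 + 1
    match_end = match_start + L - 1
    if match_start < 1 or match_end > len(u):
        raise ValueError("seed match outside the UTR")
    # helix pairs ordered by mature position: pos p pairs UTR match_end-(p-w0)
    helix = []
    for p in range(w0, w1 + 1):
        b1 = mat[p - 1]
        b2 = u[match_end - (p - w0) - 1]
        if _pair_class(b1, b2) is None:
            raise ValueError("seed window does not pair at the given match")
        helix.append((b1, b2))
    energy = params.duplex_init
    for a, b in zip(helix, helix[1:]):
        energy += _stack(params, a, b)
    # 3' extension: mature positions > w1 pair UTR positions < match_start
    s1_right = mat[w1:]
    s2_right = u[max(0, match_start - 1 - flank) : match_start - 1][::-1]
    energy += _best_extension(s1_right, s2_right, helix[-1], params)
    # 5' extension: mature positions < w0 pair UTR positions > match_end
    s1_left = mat[: w0 - 1][::-1]
    s2_left = u[match_end : match_end + flank]
    energy += _best_extension(s1_left, s2_left, helix[0], params)
    return energy


def predict_targets(
    matures: dict[str, str],
    utrs: dict[str, str],
    energy_threshold: float = DEFAULT_ENERGY_THRESHOLD,
    seed_window: tuple[int, int] = DEFAULT_SEED_WINDOW,
    allow_gu: bool = True,
    max_gu: int = 1,
    params: EnergyParameters | None = None,
    flank: int = DEFAULT_FLANK,
    gene_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Scan every (miRNA, UTR) pair and energy-score each seed match.

    Returns one row per candidate site with columns
    ``mirna_name, transcript_id, gene_name, site_start, site_end,
    seed_class, mfe, accepted, best`` where ``accepted`` requires
    mfe strictly below ``energy_threshold`` and ``best`` marks the
    lowest-energy accepted site of the pair (ties to the smallest start).
    """
    if energy_threshold >= 0:
        raise ValueError("energy threshold must be negative (kcal/mol)")
    if params is None:
        params = load_energy_parameters()
    gene_map = gene_map or {}
    rows = []
    for name in sorted(matures):
        mature = to_rna(matures[name])
        seed = extract_seed(mature, seed_window)
        for tx in sorted(utrs):
            u = to_rna(utrs[tx])
            best_key: tuple[float, int] | None = None
            pair_rows = []
            for hit in seed_match_scan(seed, u, allow_gu=allow_gu, max_gu=max_gu):
                mfe = site_energy(
                    mature, u, hit.start, params=params,
                    seed_window=seed_window, flank=flank,
                )
                accepted = mfe < energy_threshold
                pair_rows.append(
                    {
                        "mirna_name": name,
                        "transcript_id": tx,
                        "gene_name": gene_map.get(tx, tx),
                        "site_start": hit.start,
                        "site_end": hit.end,
                        "seed_class": hit.seed_class,
                        "mfe": mfe,
                        "accepted": accepted,
                        "best": False,
                    }
                )
                if accepted and (best_key is None or (mfe, hit.start) < best_key):
                    best_key = (mfe, hit.start)
            for row in pair_rows:
                if best_key is not None and (row["mfe"], row["site_start"]) == best_key:
                    row["best"] = True
            rows.extend(pair_rows)
    cols = [
        "mirna_name", "transcript_id", "gene_name", "site_start", "site_end",
        "seed_class", "mfe", "accepted", "best",
    ]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(
        ["mirna_name", "transcript_id", "site_start"], ignore_index=True
    )


def summarize_targets(sites: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accepted-target counts per miRNA and accepted-miRNA counts per transcript."""
    acc = sites[sites["accepted"]]
    per_mirna = (
        acc.groupby("mirna_name")["transcript_id"].nunique().rename("n_targets")
        .reset_index()
    )
    per_tx = (
        acc.groupby("transcript_id")["mirna_name"].nunique().rename("n_mirnas")
        .reset_index()
    )
    return per_mirna, per_tx


def conservation_check(
    seed: str, orthologs: dict[str, str]
) -> dict:
    """Presence of an all-Watson-Crick seed-complement site per species.

    ``orthologs`` maps species label -> 3'-UTR sequence. The site is
    conserved when every species carries at least one exact
    reverse-complement of the seed.
    """
    if len(orthologs) < 2:
        raise ValueError("conservation check needs at least 2 species")
    site = reverse_complement_rna(seed)
    report: dict = {"seed": to_rna(seed), "site": site, "species": {}}
    for species, seq in orthologs.items():
        u = to_rna(seq)
        positions = []
        start = u.find(site)
        while start != -1:
            positions.append(start + 1)
            start = u.find(site, start + 1)
        report["species"][species] = {
            "present": bool(positions),
            "positions": positions,
        }
    report["n_species"] = len(orthologs)
    report["n_with_site"] = sum(
        1 for v in report["species"].values() if v["present"]
    )
    report["conserved"] = report["n_with_site"] == report["n_species"]
    return report
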