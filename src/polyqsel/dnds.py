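"""Pairwise dN/dS estimation on codon alignments, by counting.

Two estimators are implemented from first principles:

* **NG86** — unweighted counting in the style of Nei & Gojobori: each of a
  codon's nine single-nucleotide neighbours carries weight 1/3 at its
  position; observed differences are averaged over all substitution
  pathways; proportions are corrected with the Jukes-Cantor formula.
* **YN00** — the counting method of Yang & Nielsen: single-nucleotide
  changes are weighted by the transition/transversion rate ratio kappa and
  by F3x4 codon frequencies (position-specific nucleotide frequencies);
  kappa is estimated from fourfold-degenerate and nondegenerate sites with
  a K80 correction; distances use a K80-style (HKY-flavoured) correction
  on the transition/transversion split of the differences.

Stop-codon convention (both estimators): a single-nucleotide change that
creates a stop codon is excluded from the numerator *and* from the site
total, so a codon may carry fewer than 3 counted sites; substitution
pathways passing through a stop codon are skipped and the remaining
pathways re-averaged. Any codon column with a gap, an ambiguity, or a stop
in either compared sequence is dropped for that pair only (pairwise
deletion).
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seq_io import GeneticCode, STANDARD_CODE, TrioAlignment

__all__ = [
    "DnDsEstimate",
    "RegionMask",
    "GeneDnDs",
    "CODONS",
    "ng86_sites",
    "ng86_differences",
    "dnds_ng86",
    "yn00_kappa",
    "dnds_yn00",
    "gene_dnds",
    "codon_pairs_from_columns",
]

NT = "TCAG"
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

#: The 61 sense codons of the standard code, in TCAG order.
CODONS: tuple[str, ...] = tuple(
    c
    for c in ("".join(t) for t in itertools.product(NT, repeat=3))
    if c not in STANDARD_CODE.stops
)


def is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


def _neighbours(codon: str) -> list[tuple[int, str, str]]:
    """(position, target codon, target nucleotide) for all 9 single-nt changes."""
    out = []
    for pos in range(3):
        for nt in NT:
            if nt != codon[pos]:
                out.append((pos, codon[:pos] + nt + codon[pos + 1 :], nt))
    return out


@lru_cache(maxsize=None)
def ng86_sites(codon: str, _code_id: int = 1) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    Each non-stop single-nucleotide neighbour contributes 1/3 to the
    synonymous count if it preserves the amino acid, else to the
    nonsynonymous count; changes to stops are dropped from both, so
    ``s + n <= 3``.
    """
    code = STANDARD_CODE
    if code.is_stop(codon) or any(c not in NT for c in codon):
        raise ValueError(f"not an unambiguous sense codon: {codon!r}")
    aa = code.amino_acid(codon)
    s = n = 0.0
    for _pos, target, _nt in _neighbours(codon):
        if code.is_stop(target):
            continue
        if code.amino_acid(target) == aa:
            s += 1.0 / 3.0
        else:
            n += 1.0 / 3.0
    return s, n


@dataclass(frozen=True)
class _PathwayCounts:
    sd: float
    nd: float
    sd_ts: float
    sd_tv: float
    nd_ts: float
    nd_tv: float
    n_paths: int  # stop-free pathways found


def _pathway_counts(
    c1: str,
    c2: str,
    kappa: float,
    pos_freqs: Sequence[Mapping[str, float]] | None,
) -> _PathwayCounts:
    """Average synonymous/nonsynonymous step counts over substitution
    pathways from ``c1`` to ``c2``, weighting each pathway by the product
    of its per-step mutation weights (kappa for transitions, target
    nucleotide frequency under F3x4). Pathways through stop codons are
    skipped; with ``kappa=1`` and no frequencies this is the unweighted
    NG86 average."""
    code = STANDARD_CODE
    diff_positions = [i for i in range(3) if c1[i] != c2[i]]
    k = len(diff_positions)
    if k == 0:
        return _PathwayCounts(0, 0, 0, 0, 0, 0, 1)
    acc = np.zeros(6)
    total_weight = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_positions):
        current = c1
        weight = 1.0
        steps = np.zeros(6)
        valid = True
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if code.is_stop(nxt):
                valid = False
                break
            ts = is_transition(current[pos], c2[pos])
            syn = code.amino_acid(current) == code.amino_acid(nxt)
            w = kappa if ts else 1.0
            if pos_freqs is not None:
                w *= pos_freqs[pos].get(c2[pos], 0.0)
            weight *= w
            if syn:
                steps[0] += 1
                steps[2 if ts else 3] += 1
            else:
                steps[1] += 1
                steps[4 if ts else 5] += 1
            current = nxt
        if valid and weight > 0.0:
            acc += weight * steps
            total_weight += weight
            n_paths += 1
    if n_paths == 0 or total_weight <= 0.0:
        return _PathwayCounts(0, 0, 0, 0, 0, 0, 0)
    acc /= total_weight
    return _PathwayCounts(*acc, n_paths)


@lru_cache(maxsize=None)
def ng86_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged synonymous and nonsynonymous difference counts
    between two sense codons (all orderings equally weighted, stop
    pathways skipped; ``sd + nd`` equals the number of differing positions
    when a stop-free pathway exists)."""
    for c in (c1, c2):
        if STANDARD_CODE.is_stop(c) or any(x not in NT for x in c):
            raise ValueError(f"not an unambiguous sense codon: {c!r}")
    pc = _pathway_counts(c1, c2, kappa=1.0, pos_freqs=None)
    if pc.n_paths == 0:
        warnings.warn(
            f"no stop-free substitution pathway between {c1} and {c2}; "
            "pair contributes zero differences"
        )
    return pc.sd, pc.nd


@dataclass
class DnDsEstimate:
    """Site counts, difference counts, corrected distances and omega."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float | None
    pN: float | None
    dS: float | None
    dN: float | None
    omega: float | None
    kappa: float | None
    status: str  # ok | NA_zero_dS | NA_saturated | NA_empty
    n_codons: int
    estimator: str
    converged: bool = True

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass(frozen=True)
class RegionMask:
    """Codon-column indices defining the region an estimate covers."""

    columns: tuple[int, ...]
    label: str = "custom"

    @classmethod
    def from_indices(cls, indices: Iterable[int], label: str = "custom") -> "RegionMask":
        return cls(tuple(sorted(set(indices))), label)


def _clean_codon_pairs(
    codons1: Sequence[str], codons2: Sequence[str]
) -> list[tuple[str, str]]:
    """Pairwise deletion: drop columns with gaps, ambiguity or stops."""
    if len(codons1) != len(codons2):
        raise ValueError("sequences cover different numbers of codons")
    ok = []
    for c1, c2 in zip(codons1, codons2):
        if any(x not in NT for x in c1 + c2):
            continue
        if STANDARD_CODE.is_stop(c1) or STANDARD_CODE.is_stop(c2):
            continue
        ok.append((c1, c2))
    return ok


def _split_codons(seq: str) -> list[str]:
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not a multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def _as_codon_pairs(pair1, pair2) -> list[tuple[str, str]]:
    c1 = _split_codons(pair1) if isinstance(pair1, str) else list(pair1)
    c2 = _split_codons(pair2) if isinstance(pair2, str) else list(pair2)
    return _clean_codon_pairs(c1, c2)


def _jc_correct(p: float) -> float | None:
    """Jukes-Cantor multiple-hit correction; None when saturated."""
    if p == 0.0:
        return 0.0
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return None
    return -0.75 * math.log(arg)


def _k80_correct(P: float, Q: float) -> float | None:
    """K80 distance from transition (P) and transversion (Q) proportions."""
    if P == 0.0 and Q == 0.0:
        return 0.0
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0.0 or b <= 0.0:
        return None
    return -0.5 * math.log(a) - 0.25 * math.log(b)


def _finalize(
    S: float,
    N: float,
    Sd: float,
    Nd: float,
    dS: float | None,
    dN: float | None,
    saturated: bool,
    kappa: float | None,
    n_codons: int,
    estimator: str,
    converged: bool = True,
) -> DnDsEstimate:
    pS = Sd / S if S > 0 else None
    pN = Nd / N if N > 0 else None
    if S <= 0 or N <= 0:
        status, omega = "NA_zero_dS", None
    elif saturated or dS is None or dN is None:
        status, omega, dS, dN = "NA_saturated", None, dS, dN
    elif dS == 0.0:
        status, omega = "NA_zero_dS", None
    else:
        status, omega = "ok", dN / dS
    return DnDsEstimate(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, dS=dS, dN=dN, omega=omega,
        kappa=kappa, status=status, n_codons=n_codons, estimator=estimator,
        converged=converged,
    )


def dnds_ng86(pair1, pair2) -> DnDsEstimate:
    """NG86 estimate for two gap-free codon sequences (strings or codon
    lists); columns with gaps/ambiguity/stops are dropped pairwise."""
    pairs = _as_codon_pairs(pair1, pair2)
    if not pairs:
        return DnDsEstimate(
            S=0, N=0, Sd=0, Nd=0, pS=None, pN=None, dS=None, dN=None,
            omega=None, kappa=None, status="NA_empty", n_codons=0,
            estimator="ng86",
        )
    counts = Counter(pairs)
    S = N = Sd = Nd = 0.0
    for (c1, c2), m in counts.items():
        s1, n1 = ng86_sites(c1)
        s2, n2 = ng86_sites(c2)
        S += m * (s1 + s2) / 2.0
        N += m * (n1 + n2) / 2.0
        if c1 != c2:
            sd, nd = ng86_differences(c1, c2)
            Sd += m * sd
            Nd += m * nd
    dS = _jc_correct(Sd / S) if S > 0 else None
    dN = _jc_correct(Nd / N) if N > 0 else None
    saturated = (S > 0 and dS is None) or (N > 0 and dN is None)
    return _finalize(S, N, Sd, Nd, dS, dN, saturated, None, len(pairs), "ng86")


# ---------------------------------------------------------------------------
# YN00-style estimator
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _degeneracy(codon: str, pos: int) -> int:
    """Number of synonymous changes (of 3) at ``pos``; 0 = nondegenerate,
    3 = fourfold-degenerate. Stop-creating changes count as nonsynonymous
    for classification."""
    aa = STANDARD_CODE.amino_acid(codon)
    syn = 0
    for nt in NT:
        if nt == codon[pos]:
            continue
        target = codon[: pos] + nt + codon[pos + 1 :]
        if not STANDARD_CODE.is_stop(target) and STANDARD_CODE.amino_acid(target) == aa:
            syn += 1
    return syn


_KAPPA_CAP = 99.0


def _k80_kappa(P: float, Q: float) -> float | None:
    """K80 transition/transversion rate ratio from proportions P, Q."""
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0.0 or b <= 0.0:
        return None
    alpha_t = -0.5 * math.log(a) + 0.25 * math.log(b)
    beta_t = -0.25 * math.log(b)
    if beta_t <= 0.0:
        return _KAPPA_CAP if alpha_t > 0.0 else None
    return min(max(alpha_t / beta_t, 0.0), _KAPPA_CAP)


def yn00_kappa(pair1, pair2) -> float:
    """Estimate kappa from nondegenerate and fourfold-degenerate sites.

    Within each site class, transition and transversion proportions are
    corrected with the K80 model; the two class estimates are combined
    weighted by class size. Falls back to ``kappa=1`` (with a warning)
    when both classes are empty or saturated.
    """
    pairs = _as_codon_pairs(pair1, pair2)
    # class -> [n_sites, n_transitions, n_transversions]
    tallies = {0: [0, 0, 0], 3: [0, 0, 0]}
    for c1, c2 in pairs:
        for pos in range(3):
            d1, d2 = _degeneracy(c1, pos), _degeneracy(c2, pos)
            if d1 == d2 and d1 in tallies:
                t = tallies[d1]
                t[0] += 1
                if c1[pos] != c2[pos]:
                    t[1 if is_transition(c1[pos], c2[pos]) else 2] += 1
    estimates = []
    for d, (n, ts, tv) in tallies.items():
        if n == 0:
            continue
        k = _k80_kappa(ts / n, tv / n)
        if k is not None:
            estimates.append((n, k))
    if not estimates:
        warnings.warn("kappa not estimable (empty/saturated site classes); using 1")
        return 1.0
    total = sum(n for n, _ in estimates)
    return sum(n * k for n, k in estimates) / total


def _position_freqs(pairs: Sequence[tuple[str, str]]) -> list[dict[str, float]]:
    """Position-specific nucleotide frequencies pooled over both sequences
    (the F3x4 ingredients)."""
    freqs = []
    for pos in range(3):
        counts = Counter()
        for c1, c2 in pairs:
            counts[c1[pos]] += 1
            counts[c2[pos]] += 1
        total = sum(counts.values())
        freqs.append({nt: counts.get(nt, 0) / total for nt in NT})
    return freqs


_UNIFORM_FREQS = [{nt: 0.25 for nt in NT} for _ in range(3)]


def _weighted_sites(
    codon: str, kappa: float, pos_freqs: Sequence[Mapping[str, float]]
) -> tuple[float, float]:
    """Mutation-weighted site counts of one codon: at each position the
    three alternative targets get weight kappa^(is_ts) x pi_pos(target);
    stop targets stay in the normalisation but score nothing, mirroring
    the NG86 stop convention (reduces exactly to NG86 at kappa=1 with
    uniform frequencies)."""
    aa = STANDARD_CODE.amino_acid(codon)
    s = n = 0.0
    for pos in range(3):
        total_w = syn_w = nonsyn_w = 0.0
        for nt in NT:
            if nt == codon[pos]:
                continue
            w = (kappa if is_transition(codon[pos], nt) else 1.0) * pos_freqs[pos].get(
                nt, 0.0
            )
            total_w += w
            target = codon[:pos] + nt + codon[pos + 1 :]
            if STANDARD_CODE.is_stop(target):
                continue
            if STANDARD_CODE.amino_acid(target) == aa:
                syn_w += w
            else:
                nonsyn_w += w
        if total_w > 0.0:
            s += syn_w / total_w
            n += nonsyn_w / total_w
    return s, n


def dnds_yn00(
    pair1,
    pair2,
    kappa: float | None = None,
    codon_freqs: str = "f3x4",
    tol: float = 1e-6,
    max_iter: int = 100,
) -> DnDsEstimate:
    """YN00-style counting estimate for two gap-free codon sequences.

    ``kappa=None`` estimates kappa from the data (fourfold/nondegenerate
    site classes, K80-corrected); ``codon_freqs`` is ``"f3x4"`` (position
    -specific nucleotide frequencies from the pair) or ``"uniform"``.
    Site and difference counting is kappa/frequency weighted; distances
    use the K80 correction on the transition/transversion split. The
    kappa/site-count loop iterates to relative convergence ``tol``.
    """
    pairs = _as_codon_pairs(pair1, pair2)
    if not pairs:
        return DnDsEstimate(
            S=0, N=0, Sd=0, Nd=0, pS=None, pN=None, dS=None, dN=None,
            omega=None, kappa=kappa, status="NA_empty", n_codons=0,
            estimator="yn00",
        )
    pos_freqs = _UNIFORM_FREQS if codon_freqs == "uniform" else _position_freqs(pairs)

    counts = Counter(pairs)
    fixed_kappa = kappa is not None
    cur_kappa = kappa if fixed_kappa else 1.0
    prev: tuple[float, float, float] | None = None
    converged = False
    S = N = 0.0
    diff = _PathwayCounts(0, 0, 0, 0, 0, 0, 1)
    for _ in range(max_iter):
        if not fixed_kappa:
            cur_kappa = yn00_kappa(
                [p[0] for p in pairs], [p[1] for p in pairs]
            )
        site_cache: dict[str, tuple[float, float]] = {}
        S = N = 0.0
        acc = np.zeros(6)
        for (c1, c2), m in counts.items():
            for c in (c1, c2):
                if c not in site_cache:
                    site_cache[c] = _weighted_sites(c, cur_kappa, pos_freqs)
            s1, n1 = site_cache[c1]
            s2, n2 = site_cache[c2]
            S += m * (s1 + s2) / 2.0
            N += m * (n1 + n2) / 2.0
            if c1 != c2:
                pc = _pathway_counts(c1, c2, cur_kappa, pos_freqs)
                acc += m * np.array(
                    [pc.sd, pc.nd, pc.sd_ts, pc.sd_tv, pc.nd_ts, pc.nd_tv]
                )
        diff = _PathwayCounts(*acc, 1)
        state = (cur_kappa, S, N)
        if prev is not None and all(
            abs(a - b) <= tol * max(1.0, abs(b)) for a, b in zip(state, prev)
        ):
            converged = True
            break
        prev = state
    else:
        warnings.warn("yn00 iteration did not converge; returning last iterate")

    Sd, Nd = diff.sd, diff.nd
    dS = _k80_correct(diff.sd_ts / S, diff.sd_tv / S) if S > 0 else None
    dN = _k80_correct(diff.nd_ts / N, diff.nd_tv / N) if N > 0 else None
    saturated = (S > 0 and dS is None) or (N > 0 and dN is None)
    return _finalize(
        S, N, Sd, Nd, dS, dN, saturated, cur_kappa, len(pairs), "yn00",
        converged=converged or fixed_kappa,
    )


# ---------------------------------------------------------------------------
# Per-gene estimates over ortholog trios
# ---------------------------------------------------------------------------

SPECIES_PAIRS_ALL = (("human", "mouse"), ("human", "rat"), ("mouse", "rat"))
SPECIES_PAIRS_HUMAN = (("human", "mouse"), ("human", "rat"))


@dataclass
class GeneDnDs:
    """Pairwise estimates for one gene/region plus their omega average."""

    gene_id: str
    label: str
    estimator: str
    per_pair: dict[tuple[str, str], DnDsEstimate]
    omega_mean: float | None
    n_pairs_ok: int


def codon_pairs_from_columns(
    trio: TrioAlignment, sp1: str, sp2: str, columns: Iterable[int]
) -> tuple[list[str], list[str]]:
    c1, c2 = [], []
    for col in columns:
        c1.append(trio.codon(sp1, col))
        c2.append(trio.codon(sp2, col))
    return c1, c2


def gene_dnds(
    trio: TrioAlignment,
    mask: RegionMask,
    estimator: str = "yn00",
    pairs: str = "all",
) -> GeneDnDs:
    """Pairwise dN/dS over the masked codon columns of a trio.

    The gene/region omega is the arithmetic mean of omega over species
    pairs with status ``ok`` (``pairs="all"`` uses human-mouse, human-rat
    and mouse-rat; ``"human_only"`` drops the rodent pair); all-NA gives
    ``None``.
    """
    if estimator not in ("yn00", "ng86"):
        raise ValueError(f"unknown estimator {estimator!r}")
    pair_set = SPECIES_PAIRS_ALL if pairs == "all" else SPECIES_PAIRS_HUMAN
    per_pair = {}
    for sp1, sp2 in pair_set:
        c1, c2 = codon_pairs_from_columns(trio, sp1, sp2, mask.columns)
        est = dnds_yn00(c1, c2) if estimator == "yn00" else dnds_ng86(c1, c2)
        per_pair[(sp1, sp2)] = est
    omegas = [e.omega for e in per_pair.values() if e.ok]
    return GeneDnDs(
        gene_id=trio.gene_id,
        label=mask.label,
        estimator=estimator,
        per_pair=per_pair,
        omega_mean=float(np.mean(omegas)) if omegas else None,
        n_pairs_ok=len(omegas),
    )
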