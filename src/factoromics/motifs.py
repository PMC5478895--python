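"""Discriminative promoter-motif discovery and simplified motif matching.

The search enumerates all short words (default length 3-8) present in a
positive promoter set, scores each word by a one-sided Fisher exact test on
sequence containment (how many positive vs control promoters contain the
word on either strand), greedily generalizes the best word with IUPAC
wildcards while the Fisher P improves, and reports the motif when its
E-value (best P times the number of exact candidate words evaluated) clears
the cutoff.  Reported motif sites are erased and the search repeats, so
successive motifs describe disjoint signal.

Found motifs carry a position weight matrix (PWM) built from their hit
sites; :func:`match_motifs` compares found PWMs to a reference collection by
best ungapped alignment (both strands) under mean per-column Pearson
correlation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MotifModel", "find_motifs", "match_motifs", "reverse_complement_pwm"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_CODE_FOR = {frozenset(v): k for k, v in IUPAC.items()}
BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def reverse_complement(word: str) -> str:
    return word.translate(_COMPLEMENT)[::-1]


def _canonical(word: str) -> str:
    rc = reverse_complement(word)
    return word if word <= rc else rc


@dataclasses.dataclass
class MotifModel:
    """A reported discriminative motif."""

    word: str  # IUPAC string
    positive_hits: int
    positive_total: int
    control_hits: int
    control_total: int
    fisher_p: float
    e_value: float
    pwm: np.ndarray  # 4 x len(word), rows A,C,G,T, columns sum to 1
    n_candidates: int

    def __post_init__(self) -> None:
        if self.positive_hits > self.positive_total or self.control_hits > self.control_total:
            raise ValueError("hit counts exceed totals")


def _validate_sequences(seqs: dict[str, str]) -> None:
    for name, seq in seqs.items():
        if set(seq) - set("ACGT"):
            bad = sorted(set(seq) - set("ACGT"))
            raise ValueError(f"sequence {name!r} contains non-ACGT characters {bad}")


def _containment_sets(
    seqs: list[str], min_len: int, max_len: int
) -> dict[int, dict[str, set[int]]]:
    """Per word length, canonical word -> indices of sequences containing it
    on either strand.  Erased positions (non-ACGT) break words."""
    by_len: dict[int, dict[str, set[int]]] = {L: {} for L in range(min_len, max_len + 1)}
    for i, seq in enumerate(seqs):
        rc = reverse_complement(seq)
        n = len(seq)
        for L in range(min_len, max_len + 1):
            table = by_len[L]
            seen: set[str] = set()
            for j in range(n - L + 1):
                w = seq[j : j + L]
                if "X" in w:
                    continue
                c = w
                r = rc[n - j - L : n - j]
                if r < c:
                    c = r
                seen.add(c)
            for c in seen:
                table.setdefault(c, set()).add(i)
    return by_len


def _fisher_sf(k: np.ndarray, pos_total: int, ctl: np.ndarray, ctl_total: int) -> np.ndarray:
    """One-sided Fisher exact P for enrichment in positives: the upper
    hypergeometric tail of the 2x2 sequence-containment table."""
    K = k + ctl
    N = pos_total + ctl_total
    return stats.hypergeom.sf(k - 1, N, K, pos_total)


def _pattern_hits(
    pattern: str, tables: dict[str, set[int]], other: dict[str, set[int]]
) -> tuple[set[int], set[int]]:
    """Union of containment sets over all exact expansions of an IUPAC pattern."""
    choices = [IUPAC[c] for c in pattern]
    n_exp = int(np.prod([len(c) for c in choices]))
    if n_exp > 4096:
        raise ValueError(f"pattern {pattern!r} too degenerate to expand")
    pos: set[int] = set()
    ctl: set[int] = set()
    words = [""]
    for c in choices:
        words = [w + b for w in words for b in c]
    for w in words:
        cw = _canonical(w)
        pos |= tables.get(cw, set())
        ctl |= other.get(cw, set())
    return pos, ctl


def _generalize(
    word: str,
    pos_tables: dict[str, set[int]],
    ctl_tables: dict[str, set[int]],
    pos_total: int,
    ctl_total: int,
    max_rounds: int = 4,
) -> tuple[str, set[int], set[int], float]:
    """Greedy single-position IUPAC substitution while Fisher P improves."""
    pattern = word
    pos_hits, ctl_hits = _pattern_hits(pattern, pos_tables, ctl_tables)
    best_p = float(
        _fisher_sf(np.array([len(pos_hits)]), pos_total, np.array([len(ctl_hits)]), ctl_total)[0]
    )
    for _ in range(max_rounds):
        improved = False
        candidates = []
        for i, cur in enumerate(pattern):
            cur_bases = frozenset(IUPAC[cur])
            for code, bases in IUPAC.items():
                bset = frozenset(bases)
                if bset <= cur_bases or not bset > cur_bases:
                    continue
                candidates.append(pattern[:i] + code + pattern[i + 1 :])
        for cand in sorted(candidates):
            try:
                p_hits, c_hits = _pattern_hits(cand, pos_tables, ctl_tables)
            except ValueError:
                continue
            p = float(
                _fisher_sf(
                    np.array([len(p_hits)]), pos_total, np.array([len(c_hits)]), ctl_total
                )[0]
            )
            if p < best_p:
                best_p, pattern, pos_hits, ctl_hits = p, cand, p_hits, c_hits
                improved = True
        if not improved:
            break
    return pattern, pos_hits, ctl_hits, best_p


def _matches(pattern: str, word: str) -> bool:
    return all(b in IUPAC[c] for c, b in zip(pattern, word))


def _build_pwm(pattern: str, sequences: list[str], pseudocount: float = 0.25) -> np.ndarray:
    """PWM from all sites matching the pattern (either strand) in the
    positive sequences; columns normalized to sum to 1."""
    L = len(pattern)
    counts = np.full((4, L), pseudocount)
    for seq in sequences:
        rc = reverse_complement(seq)
        for s in (seq, rc):
            for j in range(len(s) - L + 1):
                w = s[j : j + L]
                if "X" in w:
                    continue
                if _matches(pattern, w):
                    for col, b in enumerate(w):
                        counts[_BASE_INDEX[b], col] += 1
    return counts / counts.sum(axis=0, keepdims=True)


def _erase_sites(pattern: str, sequences: list[str]) -> list[str]:
    L = len(pattern)
    out = []
    for seq in sequences:
        chars = list(seq)
        rc = reverse_complement(seq)
        n = len(seq)
        for j in range(n - L + 1):
            w = seq[j : j + L]
            if "X" not in w and (_matches(pattern, w) or _matches(pattern, rc[n - j - L : n - j])):
                for k in range(j, j + L):
                    chars[k] = "X"
        out.append("".join(chars))
    return out


def find_motifs(
    positives: dict[str, str],
    controls: dict[str, str],
    min_len: int = 3,
    max_len: int = 8,
    e_cutoff: float = 1e-3,
    max_motifs: int = 10,
) -> list[MotifModel]:
    """Enumerate discriminative motifs in ``positives`` against ``controls``.

    Deterministic given the inputs: ties between equally significant words
    break lexicographically.  Returned motifs are ordered as found, with
    E-values monotone non-decreasing.
    """
    if not positives or not controls:
        raise ValueError("positive and control sets must both be non-empty")
    _validate_sequences(positives)
    _validate_sequences(controls)
    pos_seqs = [positives[k] for k in sorted(positives)]
    ctl_seqs = [controls[k] for k in sorted(controls)]
    pos_total, ctl_total = len(pos_seqs), len(ctl_seqs)

    motifs: list[MotifModel] = []
    for _ in range(max_motifs):
        pos_by_len = _containment_sets(pos_seqs, min_len, max_len)
        ctl_by_len = _containment_sets(ctl_seqs, min_len, max_len)

        # candidate words: every distinct canonical word present in positives
        words: list[str] = []
        k_pos: list[int] = []
        k_ctl: list[int] = []
        for L in range(min_len, max_len + 1):
            for w in sorted(pos_by_len[L]):
                words.append(w)
                k_pos.append(len(pos_by_len[L][w]))
                k_ctl.append(len(ctl_by_len[L].get(w, ())))
        if not words:
            break
        n_candidates = len(words)
        pvals = _fisher_sf(np.array(k_pos), pos_total, np.array(k_ctl), ctl_total)
        order = np.lexsort((np.array(words, dtype=object), pvals))
        best_i = order[0]
        best_word = words[best_i]

        L = len(best_word)
        pattern, pos_hits, ctl_hits, best_p = _generalize(
            best_word, pos_by_len[L], ctl_by_len[L], pos_total, ctl_total
        )
        e_value = best_p * n_candidates
        if e_value >= e_cutoff:
            break
        pwm = _build_pwm(pattern, pos_seqs)
        motifs.append(
            MotifModel(
                word=pattern,
                positive_hits=len(pos_hits),
                positive_total=pos_total,
                control_hits=len(ctl_hits),
                control_total=ctl_total,
                fisher_p=best_p,
                e_value=e_value,
                pwm=pwm,
                n_candidates=n_candidates,
            )
        )
        pos_seqs = _erase_sites(pattern, pos_seqs)
    return motifs


# ---------------------------------------------------------------------------
# motif matching (simplified reference lookup)
# ---------------------------------------------------------------------------


def reverse_complement_pwm(pwm: np.ndarray) -> np.ndarray:
    return pwm[::-1, ::-1]


def _alignment_score(a: np.ndarray, b: np.ndarray, min_overlap: int = 4) -> float:
    """Best mean per-column Pearson correlation over ungapped offsets."""
    best = -np.inf
    la, lb = a.shape[1], b.shape[1]
    min_overlap = min(min_overlap, la, lb)
    for offset in range(-(lb - min_overlap), la - min_overlap + 1):
        lo_a, hi_a = max(0, offset), min(la, offset + lb)
        cols_a = a[:, lo_a:hi_a]
        cols_b = b[:, lo_a - offset : hi_a - offset]
        corrs = []
        for j in range(cols_a.shape[1]):
            x, y = cols_a[:, j], cols_b[:, j]
            if np.std(x) == 0 or np.std(y) == 0:
                corrs.append(1.0 if np.allclose(x, y) else 0.0)
            else:
                corrs.append(float(np.corrcoef(x, y)[0, 1]))
        score = float(np.mean(corrs))
        best = max(best, score)
    return best


def match_motifs(
    found: list[MotifModel],
    reference: dict[str, np.ndarray],
    score_threshold: float = 0.8,
    min_overlap: int = 4,
) -> pd.DataFrame:
    """Best-scoring reference motif for each found motif (both strands).

    Reference PWMs must be column-stochastic 4 x L arrays (rows A,C,G,T).
    Rows with best score below ``score_threshold`` report no match.
    """
    for name, pwm in reference.items():
        if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError(f"reference PWM {name!r} columns must sum to 1")
    rows = []
    for motif in found:
        best_name, best_score = None, -np.inf
        for name in sorted(reference):
            ref = reference[name]
            score = max(
                _alignment_score(motif.pwm, ref, min_overlap),
                _alignment_score(motif.pwm, reverse_complement_pwm(ref), min_overlap),
            )
            if score > best_score:
                best_name, best_score = name, score
        rows.append(
            {
                "motif": motif.word,
                "best_match": best_name if best_score >= score_threshold else None,
                "score": best_score,
            }
        )
    return pd.DataFrame(rows)
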