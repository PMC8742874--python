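"""Position-weight-matrix and consensus motif scanning.

A motif is scored against every sequence window by log-odds (bits) of the
position probabilities against a background composition; windows at or
above a threshold — absolute bits or a fraction of the maximum attainable
score — become :class:`~remotif.core.MotifHit` records. An exact-match
IUPAC consensus mode covers (U)GCAUG-style analyses where a single element
defines the motif.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomicInterval, MotifHit, SequenceRecord, reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class PWM:
    """Position probability matrix with background and pseudocount.

    ``probs`` has one row per motif position, columns A, C, G, T. The
    pseudocount is scaled by the background when forming log-odds so that
    zero cells in database matrices stay finite.
    """

    name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError("probs must be an L x 4 matrix with L >= 1")
        if np.any(self.probs < 0) or np.any(self.background < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each probability row must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_consensus(cls, name: str, consensus: str, match_prob: float = 1.0,
                       **kwargs) -> "PWM":
        """Build a PWM from an IUPAC consensus: allowed bases share
        ``match_prob`` uniformly, the rest share the remainder."""
        consensus = consensus.upper()
        rows = []
        for ch in consensus:
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC character {ch!r} in consensus")
            allowed = [_BASE_INDEX[b] for b in IUPAC[ch]]
            row = np.full(4, (1.0 - match_prob) / 4)
            row[allowed] += match_prob / len(allowed)
            rows.append(row)
        return cls(name, np.array(rows), **kwargs)


def log_odds(pwm: PWM) -> np.ndarray:
    """Log-odds score matrix in bits.

    entry(i, b) = log2((p(i,b) + c*bg(b)) / ((1+c) * bg(b))) with
    pseudocount c; -inf where p = 0 and c = 0.
    """
    if np.any(pwm.background == 0):
        raise ValueError("background contains a zero entry")
    c = pwm.pseudocount
    num = pwm.probs + c * pwm.background
    den = (1.0 + c) * pwm.background
    with np.errstate(divide="ignore"):
        return np.log2(num / den)


def max_score(pwm: PWM) -> float:
    """Maximum attainable log-odds score: sum of per-position maxima."""
    return float(log_odds(pwm).max(axis=1).sum())


@dataclass
class ScanSettings:
    """How to scan: log-odds PWM mode or exact IUPAC consensus mode.

    Exactly one threshold style is active in PWM mode: ``threshold_frac``
    (fraction of the maximum score, in (0, 1]) or ``threshold_bits``.
    """

    mode: str = "pwm"
    threshold_frac: float | None = 0.8
    threshold_bits: float | None = None
    both_strands: bool = False
    iupac: str | None = None
    motif_name: str | None = None  # hit name when no PWM supplies one

    def __post_init__(self) -> None:
        if self.mode not in ("pwm", "consensus"):
            raise ValueError(f"unknown scan mode {self.mode!r}")
        if self.mode == "consensus":
            if not self.iupac:
                raise ValueError("consensus mode requires an IUPAC string")
        else:
            has_frac = self.threshold_frac is not None
            has_bits = self.threshold_bits is not None
            if has_frac == has_bits:
                raise ValueError("exactly one of threshold_frac/threshold_bits required")
            if has_frac and not 0 < self.threshold_frac <= 1:
                raise ValueError("threshold_frac must lie in (0, 1]")


def resolve_threshold(pwm: PWM, settings: ScanSettings) -> float:
    """Threshold in bits: fraction-of-max resolved against the PWM."""
    if settings.threshold_bits is not None:
        return float(settings.threshold_bits)
    if settings.threshold_frac is None or settings.threshold_frac <= 0:
        raise ValueError("threshold fraction must be positive")
    return settings.threshold_frac * max_score(pwm)


def encode(seq: str) -> np.ndarray:
    """Map A/C/G/T to 0..3 and anything else (N) to -1."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Score every window; windows containing N score -inf."""
    L = lom.shape[0]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    scores = np.full(n_win, -np.inf)
    if valid.any():
        w = windows[valid]
        scores[valid] = lom[np.arange(L), w].sum(axis=1)
    return scores


def _consensus_matches(seq: str, iupac: str) -> np.ndarray:
    L = len(iupac)
    allowed = []
    for ch in iupac.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r}")
        allowed.append(IUPAC[ch])
    n_win = len(seq) - L + 1
    if n_win <= 0:
        return np.empty(0, dtype=int)
    hits = [s for s in range(n_win)
            if all(seq[s + i] in allowed[i] for i in range(L))]
    return np.asarray(hits, dtype=int)


def scan(seq: SequenceRecord, pwm: PWM | None, settings: ScanSettings) -> list[MotifHit]:
    """Locate motif instances on a sequence.

    Reverse-strand hits (when ``both_strands``) are matches of the reverse
    complement, reported in forward coordinates with strand ``-``.
    Sequences shorter than the motif yield an empty result.
    """
    if settings.mode == "consensus":
        iupac = settings.iupac.upper().replace("U", "T")
        if pwm is None:
            pwm = PWM.from_consensus(settings.motif_name or iupac, iupac)
        name = settings.motif_name or pwm.name
        L = len(iupac)
        score = max_score(pwm)
        hits = []
        for strand, s in (("+", seq.seq),
                          *((("-", reverse_complement(seq.seq)),) if settings.both_strands else ())):
            for start in _consensus_matches(s, iupac):
                if strand == "-":
                    start = seq.length - start - L
                hits.append(MotifHit(name, GenomicInterval(seq.id, int(start), int(start) + L, strand), score))
        return sorted(hits, key=lambda h: (h.interval.start, h.strand))

    lom = log_odds(pwm)
    threshold = resolve_threshold(pwm, settings)
    L = pwm.length
    hits = []
    strands = ["+", "-"] if settings.both_strands else ["+"]
    for strand in strands:
        s = seq.seq if strand == "+" else reverse_complement(seq.seq)
        scores = _window_scores(encode(s), lom)
        for start in np.nonzero(scores >= threshold)[0]:
            sc = float(scores[start])
            if strand == "-":
                start = seq.length - start - L
            hits.append(MotifHit(pwm.name, GenomicInterval(seq.id, int(start), int(start) + L, strand), sc))
    return sorted(hits, key=lambda h: (h.interval.start, h.strand))


def scan_all(seqs: list[SequenceRecord], pwm: PWM | None,
             settings: ScanSettings) -> list[MotifHit]:
    hits: list[MotifHit] = []
    for seq in seqs:
        hits.extend(scan(seq, pwm, settings))
    return hits


def read_pwm_tsv(path: str | os.PathLike, name: str | None = None,
                 **kwargs) -> PWM:
    """Read a 4-column probability TSV (columns A, C, G, T, one row per
    motif position; a header row and a leading position column are both
    accepted)."""
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if str(c).upper() in _BASE_INDEX]
    if len(cols) == 4:
        mat = df[sorted(cols, key=lambda c: _BASE_INDEX[str(c).upper()])].to_numpy(float)
    else:
        df = pd.read_csv(path, sep="\t", header=None)
        mat = df.to_numpy(float)
        if mat.shape[1] == 5:  # leading position column
            mat = mat[:, 1:]
    if name is None:
        name = os.path.splitext(os.path.basename(str(path)))[0]
    return PWM(name, mat, **kwargs)


def write_pwm_tsv(pwm: PWM, path: str | os.PathLike) -> None:
    pd.DataFrame(pwm.probs, columns=list(BASES)).to_csv(path, sep="\t", index=False)
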