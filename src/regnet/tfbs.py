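"""MATCH/P-match-style PWM scanning of promoter sequences.

A position weight matrix is held as per-position base frequencies over
A,C,G,T.  Each position carries an information weight
``I(i) = Σ_b f(i,b) ln(4 f(i,b))`` (0 at uniform positions, ln 4 at fixed
ones).  A candidate window is scored

    score = (Current - Min) / (Max - Min),
    Current = Σ_i I(i) f(i, b_i),

where Max/Min substitute each position's best/worst base, so scores live in
[0,1] with 1 at the consensus.  The core similarity score (CSS) applies the
same formula to the five consecutive highest-information positions and acts
as a cheap pre-filter; the matrix similarity score (MSS) uses the full
length.  Both strands are scanned; minus-strand hits are reported at the
plus-strand start of the window (0-based, half-open coordinates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
CORE_LENGTH = 5


@dataclass(frozen=True)
class PWM:
    id: str
    frequencies: np.ndarray  # L x 4, rows sum to 1
    information: np.ndarray  # length L
    core_start: int

    @property
    def length(self) -> int:
        return self.frequencies.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.frequencies, axis=1))


@dataclass(frozen=True)
class TFBSHit:
    pwm_id: str
    sequence_id: str
    start: int
    strand: str
    mss: float
    css: float


def build_pwm(counts, pseudocount: float = 0.01, pwm_id: str = "pwm") -> PWM:
    """Normalize an L x 4 count matrix into a PWM with information weights and core."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("counts must be an L x 4 matrix over A,C,G,T")
    if counts.shape[0] < CORE_LENGTH:
        raise ValueError(f"matrix length must be >= {CORE_LENGTH}")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(counts.sum(axis=1) <= 0):
        raise ValueError("all-zero count row")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    freqs = counts + pseudocount
    freqs /= freqs.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log(4.0 * freqs), 0.0)
    info = terms.sum(axis=1)
    window_sums = np.convolve(info, np.ones(CORE_LENGTH), mode="valid")
    core_start = int(np.argmax(window_sums))  # argmax is leftmost on ties
    return PWM(id=pwm_id, frequencies=freqs, information=info, core_start=core_start)


def _score_positions(pwm: PWM, window: str, idx: np.ndarray) -> float:
    f = pwm.frequencies[idx]
    info = pwm.information[idx]
    cols = np.array([_INDEX[b] for b in window], dtype=int)
    current = float(np.sum(info * f[np.arange(len(idx)), cols]))
    mx = float(np.sum(info * f.max(axis=1)))
    mn = float(np.sum(info * f.min(axis=1)))
    if mx == mn:
        return 1.0
    return (current - mn) / (mx - mn)


def similarity_score(pwm: PWM, window: str, positions: str = "full") -> float:
    """Normalized information-weighted similarity of one window; ``positions`` in {full, core}."""
    if positions == "full":
        if len(window) != pwm.length:
            raise ValueError("window length must equal matrix length")
        idx = np.arange(pwm.length)
    elif positions == "core":
        expect = pwm.length if len(window) == pwm.length else CORE_LENGTH
        if len(window) == pwm.length:
            window = window[pwm.core_start : pwm.core_start + CORE_LENGTH]
        elif len(window) != CORE_LENGTH:
            raise ValueError("core scoring needs a full window or a 5-mer")
        idx = np.arange(pwm.core_start, pwm.core_start + CORE_LENGTH)
    else:
        raise ValueError(f"unknown positions mode {positions!r}")
    window = window.upper()
    if any(b not in _INDEX for b in window):
        raise ValueError(f"non-ACGT symbol in window {window!r}")
    return _score_positions(pwm, window, idx)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _iter_sequences(sequences) -> Iterable[tuple[str, str]]:
    if isinstance(sequences, dict):
        yield from sequences.items()
        return
    for rec in sequences:  # Bio.SeqRecord or (id, seq) pairs
        if isinstance(rec, tuple):
            yield rec
        else:
            yield rec.id, str(rec.seq)


def scan(pwm: PWM, sequences, css_cutoff: float = 0.75, mss_cutoff: float = 0.85) -> list[TFBSHit]:
    """Scan both strands of FASTA records / (id, seq) pairs for PWM hits.

    A window is kept when its core similarity meets ``css_cutoff`` and then
    its full-matrix similarity meets ``mss_cutoff``.  Windows containing
    non-ACGT symbols are skipped (counted); sequences shorter than the matrix
    are skipped with a warning.
    """
    for name, cutoff in (("css_cutoff", css_cutoff), ("mss_cutoff", mss_cutoff)):
        if not (0.0 <= cutoff <= 1.0):
            raise ValueError(f"{name} must be in [0,1]")
    L = pwm.length
    hits: list[TFBSHit] = []
    n_skipped_windows = 0
    for seq_id, seq in _iter_sequences(sequences):
        seq = str(seq).upper()
        if len(seq) < L:
            logger.warning("sequence %s shorter than matrix (%d < %d); skipped", seq_id, len(seq), L)
            continue
        for start in range(len(seq) - L + 1):
            window = seq[start : start + L]
            if any(b not in _INDEX for b in window):
                n_skipped_windows += 1
                continue
            for strand, oriented in (("+", window), ("-", reverse_complement(window))):
                css = similarity_score(pwm, oriented, positions="core")
                if css < css_cutoff:
                    continue
                mss = similarity_score(pwm, oriented, positions="full")
                if mss < mss_cutoff:
                    continue
                hits.append(
                    TFBSHit(pwm_id=pwm.id, sequence_id=seq_id, start=start,
                            strand=strand, mss=mss, css=css)
                )
    if n_skipped_windows:
        logger.info("skipped %d windows containing non-ACGT symbols", n_skipped_windows)
    hits.sort(key=lambda h: (h.sequence_id, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# matrix readers and hit writer
# ---------------------------------------------------------------------------

def read_transfac_counts(path: str | Path, pseudocount: float = 0.01) -> PWM:
    """Plain-text count matrix: optional '>id' header, then rows 'pos A C G T'."""
    pwm_id = Path(path).stem
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                pwm_id = line[1:].split()[0]
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ValueError(f"malformed matrix row: {line!r}")
            rows.append([float(x) for x in parts[1:5]])
    return build_pwm(np.array(rows), pseudocount=pseudocount, pwm_id=pwm_id)


def read_jaspar(path: str | Path, pseudocount: float = 0.01) -> PWM:
    """JASPAR-style matrix: '>id' then four lines 'A [ 1 2 3 ]' in ACGT order."""
    pwm_id = Path(path).stem
    base_rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                pwm_id = line[1:].split()[0]
                continue
            base = line[0].upper()
            if base not in _INDEX:
                raise ValueError(f"malformed JASPAR line: {line!r}")
            nums = line[1:].replace("[", " ").replace("]", " ").split()
            base_rows[base] = [float(x) for x in nums]
    if set(base_rows) != set(ALPHABET):
        raise ValueError("JASPAR matrix must have A, C, G and T rows")
    counts = np.array([base_rows[b] for b in ALPHABET]).T
    return build_pwm(counts, pseudocount=pseudocount, pwm_id=pwm_id)


def write_bed(hits: Iterable[TFBSHit], path: str | Path, length: int) -> None:
    """Write hits as BED6: sequence, start, start+L, pwm id, 1000*mss, strand."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.start}\t{h.start + length}\t"
                f"{h.pwm_id}\t{round(1000 * h.mss)}\t{h.strand}\n"
            )
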