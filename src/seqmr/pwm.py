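"""Position weight matrices: parsing, sampling and window likelihoods.

A PWM is a per-position probability distribution over the DNA alphabet
``ACGT``.  Two text formats are supported: MEME minimal motif format and a
plain whitespace-delimited four-column (A C G T) probability matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


@dataclass(frozen=True)
class PWM:
    """A position weight matrix over {A, C, G, T}.

    Parameters
    ----------
    name:
        Text label (e.g. the transcription factor the motif models).
    matrix:
        Array of shape ``(width, 4)``; each row is a probability
        distribution over A, C, G, T.
    """

    name: str
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError(f"PWM matrix must be (width, 4), got {m.shape}")
        if np.any(m < 0):
            raise ValueError("PWM probabilities must be nonnegative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1 (±1e-9)")
        object.__setattr__(self, "matrix", m)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def sample(self, rng: np.random.Generator) -> str:
        """Draw one subsequence column-wise from the PWM."""
        idx = [rng.choice(4, p=row) for row in self.matrix]
        return "".join(ALPHABET[i] for i in idx)

    def log_likelihoods(self, sequence: str) -> np.ndarray:
        """Log P(window | PWM) for every window of the sequence.

        Returns an array of length ``len(sequence) - width + 1``.
        """
        enc = encode(sequence)
        if enc.size < self.width:
            raise ValueError(
                f"sequence of length {enc.size} shorter than motif "
                f"width {self.width}"
            )
        logm = np.log(np.clip(self.matrix, 1e-300, None))
        windows = np.lib.stride_tricks.sliding_window_view(enc, self.width)
        # gather per-position log-probs and sum across the motif
        return logm[np.arange(self.width), windows].sum(axis=1)


def encode(sequence: str) -> np.ndarray:
    """Encode an ACGT string as integer indices; rejects other characters."""
    try:
        return np.array([BASE_INDEX[b] for b in sequence.upper()], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"non-ACGT character in sequence: {e.args[0]!r}") from None


def reverse_complement(sequence: str) -> str:
    comp = str.maketrans("ACGTacgt", "TGCAtgca")
    return sequence.translate(comp)[::-1]


def read_meme(path: str | Path) -> list[PWM]:
    """Parse all motifs from a MEME minimal-format file."""
    text = Path(path).read_text()
    motifs: list[PWM] = []
    blocks = re.split(r"^MOTIF\s+", text, flags=re.M)[1:]
    for block in blocks:
        lines = block.strip().splitlines()
        name = lines[0].split()[0]
        rows: list[list[float]] = []
        in_matrix = False
        for line in lines[1:]:
            if line.lower().startswith("letter-probability"):
                in_matrix = True
                continue
            if in_matrix:
                parts = line.split()
                if len(parts) == 4:
                    rows.append([float(x) for x in parts])
                elif rows:
                    break
        if not rows:
            raise ValueError(f"motif {name!r}: no probability matrix found")
        motifs.append(PWM(name=name, matrix=np.array(rows)))
    if not motifs:
        raise ValueError(f"no MOTIF blocks in {path}")
    return motifs


def read_plain(path: str | Path, name: str | None = None) -> PWM:
    """Parse a plain whitespace-delimited 4-column (A C G T) matrix."""
    p = Path(path)
    rows = []
    for line in p.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{p}: expected 4 columns, got {len(parts)}")
        rows.append([float(x) for x in parts])
    return PWM(name=name or p.stem, matrix=np.array(rows))


def load_motif(path: str | Path, name: str | None = None) -> PWM:
    """Load a single motif, auto-detecting MEME vs plain format."""
    text = Path(path).read_text()
    if "MOTIF" in text:
        motifs = read_meme(path)
        if name is not None:
            for m in motifs:
                if m.name == name:
                    return m
            raise KeyError(f"motif {name!r} not in {path}")
        return motifs[0]
    return read_plain(path, name=name)


def bundled_motifs() -> dict[str, PWM]:
    """The bundled exposure/outcome/confounder motif fixtures.

    Synthetic PWMs modeled on the canonical GATA (exposure), TAL1
    (outcome) and SOX2 (confounder) consensus motifs; they are hand-built
    stand-ins with realistic information content, not database downloads.
    """
    root = Path(__file__).parent / "motifs"
    out: dict[str, PWM] = {}
    for role, fname in [
        ("exposure", "gata_synthetic.meme"),
        ("outcome", "tal1_synthetic.meme"),
        ("confounder", "sox2_synthetic.meme"),
    ]:
        out[role] = read_meme(root / fname)[0]
    return out
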