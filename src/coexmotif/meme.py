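"""Position probability matrices and MEME minimal-format I/O.

Only the minimal motif-exchange text format is supported (version line,
optional alphabet/strands/background, ``MOTIF`` blocks with a
``letter-probability matrix`` header).  Probabilities are written with six
decimals, which round-trips within 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, ParseError

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
UNIFORM_BACKGROUND = np.full(4, 0.25)

MIN_WIDTH = 4
MAX_WIDTH = 30
DEFAULT_PSEUDOCOUNT = 0.001


@dataclass(eq=False)
class PSSM:
    """A motif as per-position base probabilities over (A, C, G, T)."""

    id: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ContractError(f"motif {self.id}: probability matrix must be width x 4")
        if not MIN_WIDTH <= self.probs.shape[0] <= MAX_WIDTH:
            raise ContractError(
                f"motif {self.id}: width {self.probs.shape[0]} outside [{MIN_WIDTH}, {MAX_WIDTH}]"
            )
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            raise ContractError(f"motif {self.id}: probability rows must sum to 1")
        self.probs = self.probs / sums[:, None]
        if self.background.shape != (4,) or abs(self.background.sum() - 1.0) > 1e-6:
            raise ContractError(f"motif {self.id}: background must be 4 probabilities summing to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def regularized_probs(self, background: np.ndarray | None = None) -> np.ndarray:
        """Background-proportional pseudocount smoothing; rows still sum to 1."""
        bg = self.background if background is None else np.asarray(background, dtype=float)
        return (self.probs + self.pseudocount * bg[None, :]) / (1.0 + self.pseudocount)

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        """Per-position log2 odds of the regularized probabilities vs background."""
        bg = self.background if background is None else np.asarray(background, dtype=float)
        return np.log2(self.regularized_probs(bg) / bg[None, :])

    def reverse_complement(self, new_id: str | None = None) -> "PSSM":
        return PSSM(
            id=new_id if new_id is not None else self.id,
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background.copy(),
            pseudocount=self.pseudocount,
        )

    def consensus(self) -> str:
        return "".join(ALPHABET[k] for k in self.probs.argmax(axis=1))


def write_meme(pssms: list[PSSM], path, background: np.ndarray | None = None) -> None:
    """Write motifs in MEME minimal format."""
    bg = np.asarray(background, dtype=float) if background is not None else UNIFORM_BACKGROUND
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("MEME version 4\n\n")
        fh.write("ALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {bg[i]:.6f}" for i, b in enumerate(ALPHABET)) + "\n\n")
        for m in pssms:
            fh.write(f"MOTIF {m.id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width} nsites= 20 E= 0\n")
            for row in m.probs:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list[PSSM]:
    """Parse a MEME minimal-format file into a list of :class:`PSSM`.

    Malformed matrix rows raise :class:`ParseError` naming the motif id; a
    background line, when present, is attached to every motif, otherwise the
    background is uniform.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    background = UNIFORM_BACKGROUND.copy()
    motifs: list[PSSM] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            tokens: list[str] = []
            while i < n and lines[i].strip() and not lines[i].startswith(("MOTIF", "ALPHABET")):
                tokens.extend(lines[i].split())
                i += 1
            try:
                freq = {tokens[k]: float(tokens[k + 1]) for k in range(0, len(tokens), 2)}
                background = np.array([freq[b] for b in ALPHABET])
            except (ValueError, KeyError, IndexError):
                raise ParseError(f"{path}: malformed background frequency line") from None
            continue
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}: MOTIF line without an id")
            motif_id = parts[1]
            i += 1
            while i < n and "letter-probability matrix" not in lines[i]:
                if lines[i].strip().startswith("MOTIF"):
                    raise ParseError(f"{path}: motif {motif_id}: missing probability matrix")
                i += 1
            if i >= n:
                raise ParseError(f"{path}: motif {motif_id}: missing probability matrix")
            header = lines[i]
            width = None
            toks = header.replace("=", " = ").split()
            for k, tok in enumerate(toks):
                if tok == "w" and k + 2 < len(toks) and toks[k + 1] == "=":
                    width = int(toks[k + 2])
            i += 1
            rows: list[list[float]] = []
            while i < n:
                s = lines[i].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                cells = s.split()
                if len(cells) != 4:
                    raise ParseError(
                        f"{path}: motif {motif_id}: matrix row has {len(cells)} columns"
                    )
                try:
                    row = [float(c) for c in cells]
                except ValueError:
                    raise ParseError(
                        f"{path}: motif {motif_id}: non-numeric matrix entry"
                    ) from None
                if abs(sum(row) - 1.0) > 1e-3:
                    raise ParseError(f"{path}: motif {motif_id}: matrix row does not sum to 1")
                rows.append(row)
                i += 1
            if width is not None and width != len(rows):
                raise ParseError(
                    f"{path}: motif {motif_id}: declared width {width}, found {len(rows)} rows"
                )
            if not rows:
                raise ParseError(f"{path}: motif {motif_id}: empty probability matrix")
            try:
                motifs.append(PSSM(id=motif_id, probs=np.array(rows), background=background.copy()))
            except ContractError as exc:
                raise ParseError(str(exc)) from None
            continue
        i += 1
    return motifs
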