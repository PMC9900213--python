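"""Tokenization: vocabulary, peptide–kinase pair assembly, MLM corruption.

A pair is encoded as::

    <sos> p1 .. p11 <eos> <sos> k1 .. kT <eos>

so the token sequence has length ``t_peptide + t_kinase + 4`` and the
peptide's center residue (the candidate phosphosite) always sits at token
index 6. Dashes padding short peptides map to ``<pad>``; mask markers from
the kinase-masking augmentation, and unknown residues ('X'), map to
``<mask>``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import AMINO_ACIDS, MASK_CHAR, PeptideWindow, PHOSPHOACCEPTORS

PAD, SOS, EOS, MASK = "<pad>", "<sos>", "<eos>", "<mask>"
SPECIAL_TOKENS = (PAD, SOS, EOS, MASK)


@dataclass(frozen=True)
class Vocabulary:
    """Fixed residue vocabulary: 4 special tokens, 20 amino acids, and 'X'."""

    tokens: tuple[str, ...] = SPECIAL_TOKENS + tuple(AMINO_ACIDS) + ("X",)
    _ids: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._ids.update({t: i for i, t in enumerate(self.tokens)})

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self._ids[PAD]

    @property
    def sos_id(self) -> int:
        return self._ids[SOS]

    @property
    def eos_id(self) -> int:
        return self._ids[EOS]

    @property
    def mask_id(self) -> int:
        return self._ids[MASK]

    @property
    def n_special(self) -> int:
        return len(SPECIAL_TOKENS)

    def residue_id(self, aa: str) -> int:
        """Token id for one residue letter ('-' -> pad, '#'/'X' -> mask)."""
        if aa == "-":
            return self.pad_id
        if aa == MASK_CHAR or aa == "X":
            return self.mask_id
        try:
            return self._ids[aa]
        except KeyError:
            raise ValueError(f"unknown residue letter {aa!r}") from None

    @property
    def _lut(self) -> np.ndarray:
        """Byte-value lookup table for vectorized residue encoding."""
        lut = self._ids.get("__lut__")
        if lut is None:
            lut = np.full(256, 255, dtype=np.uint8)
            for aa in list(AMINO_ACIDS) + ["-", MASK_CHAR, "X"]:
                lut[ord(aa)] = self.residue_id(aa)
            self._ids["__lut__"] = lut
        return lut

    def encode_residues(self, seq: str) -> np.ndarray:
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        ids = self._lut[raw]
        if (ids == 255).any():
            bad = sorted({seq[i] for i in np.flatnonzero(ids == 255)})
            raise ValueError(f"unknown residue letter(s) {bad!r}")
        return ids.astype(np.int64)

    def encode_sequence(self, seq: str) -> np.ndarray:
        """``<sos> seq <eos>`` for single-sequence (pre-training) input."""
        return np.concatenate(
            ([self.sos_id], self.encode_residues(seq), [self.eos_id])
        ).astype(np.int64)

    def decode(self, token_id: int) -> str:
        return self.tokens[token_id]

    def decode_tokens(self, ids: Sequence[int]) -> str:
        out = []
        for i in ids:
            tok = self.tokens[int(i)]
            out.append({PAD: "-", MASK: MASK_CHAR, SOS: "", EOS: ""}.get(tok, tok))
        return "".join(out)

    def is_residue(self, ids: np.ndarray) -> np.ndarray:
        """Boolean mask of positions holding residue tokens (non-special)."""
        return np.asarray(ids) >= self.n_special

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"tokens": list(self.tokens)}, indent=1) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        data = json.loads(Path(path).read_text())
        return cls(tokens=tuple(data["tokens"]))


#: token index of the candidate phosphosite in every encoded pair
CENTER_INDEX = 6


@dataclass
class TokenizedPair:
    token_ids: np.ndarray
    center_index: int
    padding: np.ndarray  # True where the token is <pad>
    segment_ids: np.ndarray  # 0 for the peptide span, 1 for the kinase span
    t_peptide: int
    t_kinase: int


def encode_pair(
    peptide: PeptideWindow, kinase_domain: str, vocab: Vocabulary | None = None
) -> TokenizedPair:
    """Assemble the tokenized peptide–kinase pair."""
    vocab = vocab or Vocabulary()
    if not kinase_domain:
        raise ValueError("kinase domain is empty")
    pep_ids = vocab.encode_residues(peptide.residues)
    kin_ids = vocab.encode_residues(kinase_domain)
    ids = np.concatenate(
        (
            [vocab.sos_id],
            pep_ids,
            [vocab.eos_id],
            [vocab.sos_id],
            kin_ids,
            [vocab.eos_id],
        )
    ).astype(np.int64)
    assert len(ids) == len(peptide.residues) + len(kinase_domain) + 4
    center = vocab.decode(int(ids[CENTER_INDEX]))
    if center not in PHOSPHOACCEPTORS:
        raise ValueError(f"center token {center!r} is not S/T/Y")
    segments = np.zeros(len(ids), dtype=np.int64)
    segments[len(peptide.residues) + 2 :] = 1
    return TokenizedPair(
        token_ids=ids,
        center_index=CENTER_INDEX,
        padding=ids == vocab.pad_id,
        segment_ids=segments,
        t_peptide=len(peptide.residues),
        t_kinase=len(kinase_domain),
    )


@dataclass
class MLMBatch:
    """Corrupted sequences plus the bookkeeping needed for the MLM loss."""

    corrupted: list[np.ndarray]
    masked_positions: list[np.ndarray]  # indices Π per sequence
    originals: list[np.ndarray]  # true tokens at Π per sequence
    n_masked: int  # K = Σ|Π|


DEFAULT_MLM_RATE = 0.15


def mlm_corrupt(
    sequences: Sequence[np.ndarray],
    rate: float = DEFAULT_MLM_RATE,
    rng: np.random.Generator | None = None,
    vocab: Vocabulary | None = None,
) -> MLMBatch:
    """Select residue tokens i.i.d. with probability ``rate`` and replace
    them with ``<mask>``; special tokens are never selected. Originals are
    retained so the loss can score only the masked positions.
    """
    if not (0.0 < rate < 1.0):
        raise ValueError("mask rate must be in (0, 1)")
    rng = rng if rng is not None else np.random.default_rng()
    vocab = vocab or Vocabulary()
    corrupted, positions, originals = [], [], []
    total = 0
    for seq in sequences:
        seq = np.asarray(seq, dtype=np.int64)
        eligible = vocab.is_residue(seq)
        hits = eligible & (rng.random(len(seq)) < rate)
        idx = np.flatnonzero(hits)
        out = seq.copy()
        out[idx] = vocab.mask_id
        corrupted.append(out)
        positions.append(idx)
        originals.append(seq[idx])
        total += len(idx)
    return MLMBatch(
        corrupted=corrupted, masked_positions=positions, originals=originals, n_masked=total
    )


def pad_token_batch(
    sequences: Sequence[np.ndarray], vocab: Vocabulary | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad token sequences to the batch maximum.

    Returns ``(ids, attend)`` where ``attend`` is False on padding; padded
    positions are excluded from attention and from every loss.
    """
    vocab = vocab or Vocabulary()
    n, t = len(sequences), max(len(s) for s in sequences)
    ids = np.full((n, t), vocab.pad_id, dtype=np.int64)
    attend = np.zeros((n, t), dtype=bool)
    for i, s in enumerate(sequences):
        ids[i, : len(s)] = s
        attend[i, : len(s)] = True
    return ids, attend
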