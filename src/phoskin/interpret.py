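"""Phosphosite embeddings and substrate attention profiles.

Two interpretability readouts of a trained model:

* the encoder output row at the peptide-center token (the phosphosite
  embedding), exportable for 2-D projection;
* per-position attention over the 11-mer peptide in the final attention
  layer, averaged over heads and pairs — a picture of which substrate
  positions the model treats as specificity determinants.

Two aggregation modes are provided, since attention can be summarized
either as what each peptide position *receives* from all query tokens
("column-mean") or as what the center token *looks at* ("center").
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .encoding import CENTER_INDEX, TokenizedPair, Vocabulary, encode_pair
from .nn.transformer import TransformerEncoder
from .records import KinaseRecord, LabeledPair, WINDOW_SIZE

PROFILE_MODES = ("column-mean", "center")


@dataclass
class PhosphositeEmbedding:
    vector: np.ndarray  # length embed_dim
    kinase_id: str
    family: str
    group: str
    center_residue: str
    peptide: str


@dataclass
class AttentionProfile:
    """Mean attention per peptide position P−5..P+5 for one kinase."""

    values: np.ndarray  # length 11, non-negative
    kinase_id: str
    stage: str  # "pretrained" | "finetuned"
    mode: str
    n_pairs: int

    def argmax_offset(self) -> int:
        """Peptide offset (−5..+5) receiving the most attention."""
        return int(np.argmax(self.values)) - (WINDOW_SIZE // 2)

    def at_offset(self, offset: int) -> float:
        return float(self.values[offset + WINDOW_SIZE // 2])


def extract_phosphosite_embedding(
    model: TransformerEncoder,
    pair: TokenizedPair,
    kinase: KinaseRecord | None = None,
    vocab: Vocabulary | None = None,
) -> PhosphositeEmbedding:
    """Encoder output at the center token plus projection metadata."""
    vocab = vocab or Vocabulary()
    hidden, _ = model.forward(
        pair.token_ids[None, :], np.ones((1, len(pair.token_ids)), bool), pair.segment_ids[None, :]
    )
    vec = hidden.data[0, pair.center_index].copy()
    return PhosphositeEmbedding(
        vector=vec,
        kinase_id=kinase.kinase_id if kinase else "",
        family=kinase.family if kinase else "",
        group=kinase.group if kinase else "",
        center_residue=vocab.decode(int(pair.token_ids[pair.center_index])),
        peptide=vocab.decode_tokens(pair.token_ids[1 : 1 + pair.t_peptide]),
    )


def attention_profile(
    model: TransformerEncoder,
    pairs: Sequence[LabeledPair],
    kinome: Mapping[str, KinaseRecord],
    stage: str = "finetuned",
    mode: str = "column-mean",
    vocab: Vocabulary | None = None,
) -> AttentionProfile:
    """Average final-layer attention over the 11 peptide positions.

    ``column-mean``: for each peptide token, the mean attention it receives
    over all query tokens (batch-pad queries excluded), heads, and pairs.
    ``center``: the attention the center (phosphosite) query pays to each
    peptide token, averaged over heads and pairs.
    """
    if not pairs:
        raise ValueError("at least one pair is required")
    kinase_ids = {p.kinase_id for p in pairs}
    if len(kinase_ids) != 1:
        raise ValueError(f"all pairs must share one kinase, got {sorted(kinase_ids)}")
    if mode not in PROFILE_MODES:
        raise ValueError(f"mode must be one of {PROFILE_MODES}")
    vocab = vocab or Vocabulary()
    (kinase_id,) = kinase_ids
    domain = kinome[kinase_id].domain_sequence

    acc = np.zeros(WINDOW_SIZE)
    for p in pairs:
        enc = encode_pair(p.peptide, domain, vocab)
        _, attentions = model.forward(
            enc.token_ids[None, :],
            np.ones((1, len(enc.token_ids)), bool),
            enc.segment_ids[None, :],
            collect_attention=True,
        )
        final = attentions[-1][0]  # (heads, T, T)
        pep_slice = slice(1, 1 + WINDOW_SIZE)  # peptide tokens sit after <sos>
        if mode == "column-mean":
            acc += final[:, :, pep_slice].mean(axis=(0, 1))
        else:
            acc += final[:, CENTER_INDEX, pep_slice].mean(axis=0)
    return AttentionProfile(
        values=acc / len(pairs), kinase_id=kinase_id, stage=stage, mode=mode, n_pairs=len(pairs)
    )


def export_embedding_matrix(
    embeddings: Sequence[PhosphositeEmbedding],
    path: str | Path,
    project: bool = False,
) -> pd.DataFrame:
    """Write embedding vectors plus metadata as TSV for external projection.

    With ``project=True`` a 2-D UMAP projection is appended as columns
    ``umap_1``/``umap_2`` (requires the optional umap-learn package).
    """
    if len(embeddings) < 2:
        raise ValueError("at least two embeddings are required")
    dims = {len(e.vector) for e in embeddings}
    if len(dims) != 1:
        raise ValueError(f"embedding dimensions disagree: {sorted(dims)}")
    (dim,) = dims
    data = {
        "kinase_id": [e.kinase_id for e in embeddings],
        "family": [e.family for e in embeddings],
        "group": [e.group for e in embeddings],
        "center_residue": [e.center_residue for e in embeddings],
        "peptide": [e.peptide for e in embeddings],
    }
    mat = np.stack([e.vector for e in embeddings])
    for d in range(dim):
        data[f"e{d}"] = mat[:, d]
    df = pd.DataFrame(data)
    if project:
        try:
            import umap
        except ImportError as exc:  # pragma: no cover
            raise ImportError("2-D projection requires the optional umap-learn package") from exc
        proj = umap.UMAP(n_components=2, random_state=0).fit_transform(mat)
        df["umap_1"], df["umap_2"] = proj[:, 0], proj[:, 1]
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return df


def read_embedding_matrix(path: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    """Round-trip reader: returns (vectors, metadata)."""
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if c.startswith("e") and c[1:].isdigit()]
    cols.sort(key=lambda c: int(c[1:]))
    return df[cols].to_numpy(), df.drop(columns=cols)
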