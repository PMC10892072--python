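"""The scalar SMILES feature distilled from a sequence-embedding backend.

The classifier consumes a single number per substance: the grand mean over
all token positions and all hidden dimensions of the last-hidden-layer
embedding matrix of the SMILES string (``roberta_embedding_mean``). The
backend producing that matrix is pluggable — any object with an
``embed(smiles) -> (tokens x dims) array`` method works. The built-in
backend is a deterministic character-trigram hashing embedder, so the whole
pipeline runs offline and bit-identically across platforms; a pretrained
chemistry language model (e.g. a RoBERTa-family SMILES model with hidden
size 768) can be dropped in through the same contract.
"""

from __future__ import annotations

import hashlib
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .exceptions import BackendError, ValidationError

DEFAULT_DIM = 768


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Contract: deterministic token-by-dimension embeddings for a SMILES."""

    backend_id: str

    def embed(self, smiles: str) -> np.ndarray:  # (n_tokens, dim)
        ...


def fallback_embed(smiles: str, dim: int = DEFAULT_DIM, seed_salt: int = 0) -> np.ndarray:
    """Deterministic pseudo-embedding via character-trigram hashing.

    Each padded trigram of the SMILES is one "token"; its ``dim`` values are
    unit-interval reals derived from a BLAKE2b stream keyed by the trigram
    and ``seed_salt``. No randomness, no network, platform-independent.
    """
    if dim < 1:
        raise ValidationError("embedding dim must be >= 1")
    if not smiles:
        raise ValidationError("cannot embed an empty SMILES")
    padded = f"^{smiles}$"
    trigrams = [padded[i : i + 3] for i in range(len(padded) - 2)] or [padded]
    rows = np.empty((len(trigrams), dim))
    n_bytes = dim * 8
    for t, tri in enumerate(trigrams):
        stream = b""
        counter = 0
        while len(stream) < n_bytes:
            h = hashlib.blake2b(
                f"{seed_salt}|{tri}|{counter}".encode(), digest_size=64
            )
            stream += h.digest()
            counter += 1
        ints = np.frombuffer(stream[:n_bytes], dtype="<u8")
        rows[t] = ints / np.float64(2**64)
    return rows


class TrigramHashEmbedder:
    """Offline embedding backend built on :func:`fallback_embed`."""

    def __init__(self, dim: int = DEFAULT_DIM, seed_salt: int = 0):
        self.dim = dim
        self.seed_salt = seed_salt
        self.backend_id = f"trigram-hash-d{dim}-s{seed_salt}"

    def embed(self, smiles: str) -> np.ndarray:
        return fallback_embed(smiles, self.dim, self.seed_salt)


def smiles_scalar_feature(smiles: str, provider: EmbeddingProvider) -> float:
    """Grand mean of the provider's last-hidden-layer matrix for one SMILES.

    Mean over token positions, then over hidden dimensions — numerically the
    grand mean of all entries. Raises a backend error (never a silent
    fallback) if the provider fails.
    """
    if not smiles:
        raise ValidationError("SMILES must be non-empty")
    try:
        matrix = np.asarray(provider.embed(smiles), dtype=float)
    except ValidationError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with backend context
        raise BackendError(f"embedding backend failed for {smiles!r}: {exc}") from exc
    if matrix.ndim != 2 or matrix.shape[0] < 1:
        raise BackendError(f"backend returned shape {matrix.shape}, need (tokens, dim)")
    if not np.all(np.isfinite(matrix)):
        raise BackendError("backend returned non-finite embeddings")
    return float(matrix.mean(axis=0).mean())


def embed_table(ids, smiles_list, provider: EmbeddingProvider) -> pd.DataFrame:
    """Feature cache: one scalar per substance, with backend provenance."""
    scalars = [smiles_scalar_feature(s, provider) for s in smiles_list]
    return pd.DataFrame(
        {
            "id": list(ids),
            "smiles": list(smiles_list),
            "backend": provider.backend_id,
            "roberta_embedding_mean": scalars,
        }
    )
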