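"""Numeric encodings of mutation-pair matrices.

Three schemes are supported, all operating on the 2xL symbol matrix:

* ``label``   — each symbol becomes its integer ID (2 x L)
* ``onehot``  — each symbol becomes a 5-bit indicator block (2 x 5L)
* ``embedding`` — each symbol becomes a learned 2-vector (2 x 2L), trained
  with a word2vec-style skip-gram over single-nucleotide tokens

Label IDs follow alphabetical symbol order (a=0, c=1, g=2, n=3, t=4).  The
one-hot slot order is (n, g, t, c, a), so 'a' -> [0,0,0,0,1] and
'c' -> [0,0,0,1,0].  Both are fixed module constants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .variant_windows import ALPHABET, MutationPair, Variant

logger = logging.getLogger(__name__)

#: integer ID per symbol, alphabetical order
LABEL_IDS: dict[str, int] = {s: i for i, s in enumerate(sorted(ALPHABET))}

#: one-hot slot order: position of the 1 inside each 5-bit block
ONEHOT_SLOTS = "ngtca"

SCHEMES = ("label", "onehot", "embedding")

#: per-symbol column width of each scheme
BLOCK_SIZE = {"label": 1, "onehot": 5, "embedding": 2}


@dataclass
class EncodedSample:
    """One encoded mutation pair: a 2 x L' numeric matrix plus metadata."""

    scheme: str
    matrix: np.ndarray
    label: str
    key: str

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 2:
            raise ValueError(f"matrix must be 2 x L', got shape {self.matrix.shape}")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


def encoded_width(scheme: str, w: int) -> int:
    """Per-row width law: L for label, 5L for onehot, 2L for embedding."""
    return BLOCK_SIZE[scheme] * (2 * w + 1)


def _check_symbols(row: str) -> None:
    bad = set(row) - set(ALPHABET)
    if bad:
        raise ValueError(f"symbols outside alphabet {ALPHABET!r}: {sorted(bad)}")


def encode_label(pair: MutationPair) -> EncodedSample:
    """Integer-ID encoding, 2 x L."""
    rows = []
    for row in pair.matrix:
        _check_symbols(row)
        rows.append([LABEL_IDS[s] for s in row])
    return EncodedSample("label", np.asarray(rows, dtype=np.int64), pair.variant.label, pair.variant.key)


def encode_onehot(pair: MutationPair) -> EncodedSample:
    """Indicator-block encoding, 2 x 5L; each block sums to one."""
    eye = np.eye(5, dtype=np.int64)
    slot = {s: ONEHOT_SLOTS.index(s) for s in ALPHABET}
    rows = []
    for row in pair.matrix:
        _check_symbols(row)
        rows.append(eye[[slot[s] for s in row]].reshape(-1))
    return EncodedSample("onehot", np.stack(rows), pair.variant.label, pair.variant.key)


@dataclass
class EmbeddingModel:
    """Per-symbol 2-vectors learned by a skip-gram over nucleotide tokens."""

    vectors: dict[str, np.ndarray]
    dims: int
    seed: int
    corpus_descriptor: str = ""

    def __post_init__(self) -> None:
        missing = set(ALPHABET) - set(self.vectors)
        if missing:
            raise ValueError(f"embedding lacks vectors for {sorted(missing)}")
        for s, vec in self.vectors.items():
            if len(vec) != self.dims:
                raise ValueError(f"vector for {s!r} has length {len(vec)}, expected {self.dims}")

    def as_matrix(self) -> np.ndarray:
        return np.stack([self.vectors[s] for s in sorted(ALPHABET)])


def train_embedding(
    corpus: list[str],
    dims: int = 2,
    seed: int = 0,
    window: int = 5,
    iterations: int = 300,
    learning_rate: float = 0.2,
) -> EmbeddingModel:
    """Train a skip-gram embedding over single-symbol tokens.

    With a 5-symbol vocabulary the full-softmax skip-gram objective only
    depends on the centre/context co-occurrence counts, so those are
    accumulated once and the exact batch gradient is descended — making
    training fast and fully deterministic under the seed.  Symbols that
    never occur in the corpus keep a zero vector (logged).
    """
    if not corpus or all(len(s) == 0 for s in corpus):
        raise ValueError("empty training corpus")
    vocab = sorted(ALPHABET)
    index = {s: i for i, s in enumerate(vocab)}
    V = len(vocab)

    counts = np.zeros((V, V), dtype=np.float64)  # counts[center, context]
    for sent in corpus:
        _check_symbols(sent)
        ids = np.array([index[s] for s in sent], dtype=np.int64)
        n = len(ids)
        for off in range(1, window + 1):
            if off >= n:
                break
            np.add.at(counts, (ids[:-off], ids[off:]), 1.0)
            np.add.at(counts, (ids[off:], ids[:-off]), 1.0)

    rng = np.random.default_rng(seed)
    W_in = rng.normal(scale=0.1, size=(V, dims))
    W_out = rng.normal(scale=0.1, size=(V, dims))
    total = counts.sum()
    if total == 0:
        raise ValueError("corpus yields no skip-gram pairs (sequences too short)")

    center_counts = counts.sum(axis=1)
    for _ in range(iterations):
        logits = W_in @ W_out.T  # (V centers, V contexts)
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        # gradient of -sum counts[c,o] log p(o|c), normalized by pair count
        G = (center_counts[:, None] * p - counts) / total
        grad_in = G @ W_out
        grad_out = G.T @ W_in
        W_in -= learning_rate * grad_in
        W_out -= learning_rate * grad_out

    vectors: dict[str, np.ndarray] = {}
    for s, i in index.items():
        if center_counts[i] == 0 and counts[:, i].sum() == 0:
            logger.warning("symbol %r absent from embedding corpus; using zero vector", s)
            vectors[s] = np.zeros(dims)
        else:
            vectors[s] = W_in[i].copy()
    return EmbeddingModel(vectors=vectors, dims=dims, seed=seed,
                          corpus_descriptor=f"{len(corpus)} sequences, {int(total)} pairs")


def encode_embedding(pair: MutationPair, model: EmbeddingModel) -> EncodedSample:
    """Replace each symbol by its vector, concatenated along the row: 2 x dims*L."""
    rows = []
    for row in pair.matrix:
        _check_symbols(row)
        rows.append(np.concatenate([model.vectors[s] for s in row]))
    return EncodedSample("embedding", np.stack(rows), pair.variant.label, pair.variant.key)


def decode(sample: EncodedSample, variant: Variant | None = None) -> MutationPair:
    """Exact inverse of the label / one-hot encoders.

    Embedding samples are not invertible in general and raise.  If the
    originating variant is not supplied, a placeholder anchored at the
    centre column is reconstructed from the decoded rows.
    """
    if sample.scheme == "embedding":
        raise ValueError("embedding encoding is not invertible")
    if sample.scheme == "label":
        inv = {i: s for s, i in LABEL_IDS.items()}
        rows = ["".join(inv[int(v)] for v in row) for row in sample.matrix]
    elif sample.scheme == "onehot":
        rows = []
        for row in sample.matrix:
            blocks = np.asarray(row).reshape(-1, 5)
            if not np.all(blocks.sum(axis=1) == 1):
                raise ValueError("malformed one-hot row: block does not sum to 1")
            rows.append("".join(ONEHOT_SLOTS[j] for j in blocks.argmax(axis=1)))
    else:  # pragma: no cover - guarded in EncodedSample
        raise ValueError(f"unknown scheme {sample.scheme!r}")
    w = (len(rows[0]) - 1) // 2
    if variant is None:
        variant = Variant("decoded", w + 1, rows[0][w].upper(), rows[1][w].upper(), sample.label)
    return MutationPair(w=w, ref_row=rows[0], alt_row=rows[1], variant=variant)


def encode_pairs(
    pairs: list[MutationPair],
    scheme: str,
    model: EmbeddingModel | None = None,
    seed: int = 0,
) -> list[EncodedSample]:
    """Encode a batch of pairs under one scheme.

    For the embedding scheme a model is trained on the reference rows of the
    batch when none is supplied.
    """
    if scheme == "label":
        return [encode_label(p) for p in pairs]
    if scheme == "onehot":
        return [encode_onehot(p) for p in pairs]
    if scheme == "embedding":
        if model is None:
            model = train_embedding([p.ref_row for p in pairs], seed=seed)
        return [encode_embedding(p, model) for p in pairs]
    raise ValueError(f"unknown scheme {scheme!r}")


def stack_dataset(samples: list[EncodedSample]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack encoded samples into (X, y, keys) for model training.

    X has shape (n, 2, L'); y is 1 for drivers, 0 for passengers.
    Unlabeled samples are an error here — scoring them goes through a
    trained model instead.
    """
    if not samples:
        raise ValueError("no samples to stack")
    widths = {s.width for s in samples}
    schemes = {s.scheme for s in samples}
    if len(widths) != 1 or len(schemes) != 1:
        raise ValueError(f"samples mix schemes {schemes} or widths {widths}")
    y = []
    for s in samples:
        if s.label not in ("driver", "passenger"):
            raise ValueError(f"unlabeled sample {s.key} cannot enter a training matrix")
        y.append(1 if s.label == "driver" else 0)
    X = np.stack([s.matrix for s in samples]).astype(np.float64)
    return X, np.asarray(y, dtype=np.int64), [s.key for s in samples]
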