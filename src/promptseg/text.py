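"""Natural-language prompt construction, tokenization and embedding.

Prompts are built from class-synonym tables ("Glioma" -> "Glioma",
"Brain tumor", "Tumor", "Neoplasm", ...) substituted into templates such
as "Segment the {} region".  A prompt is tokenized (lowercased,
punctuation-split, wrapped in start/separator markers) to at most 16
positions and embedded to a fixed 768-dimensional semantic vector v_t by
mean pooling the per-token vectors over non-padding positions.

The token embedder is pluggable: anything mapping a token string to a
768-vector works.  The bundled :class:`HashEmbedder` derives each token's
vector deterministically from a salted SHA-256 hash of the token, so the
whole pipeline runs offline and reproducibly.  The embedder is frozen by
construction — it exposes no trainable parameters — which mirrors the
design in which only the downstream conditioning maps learn while the
text side stays a fixed semantic projector.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field

import numpy as np

EMBED_DIM = 768
MAX_TOKENS = 16
CLS, SEP, PAD = "[CLS]", "[SEP]", "[PAD]"

DEFAULT_TEMPLATES = [
    "Segment the {} region",
    "Identify the {}",
    "Your goal is to Spot the {}",
    "Isolate the {}",
    "Find the {} margins",
]

# Brain-lesion classes and their clinical synonyms.
BRAIN_SYNONYMS = {
    "glioma": ["Glioma", "Brain tumor", "Tumor", "Neoplasm",
               "Cerebral tumor", "Intracranial tumor"],
    "meningioma": ["Meningioma", "Meningeal tumor", "Meningeal neoplasm",
                   "Cerebral meningioma"],
    "pituitary": ["Pituitary tumor", "Pituitary adenoma",
                  "Pituitary neoplasm", "Pituitary gland tumor"],
}

# Abdominal-organ table for the multi-organ regime.
ORGAN_SYNONYMS = {
    "liver": ["Liver", "Hepatic organ", "Hepatic parenchyma"],
    "spleen": ["Spleen", "Splenic organ"],
    "right_kidney": ["Right kidney", "Right renal organ"],
    "left_kidney": ["Left kidney", "Left renal organ"],
}


@dataclass
class SynonymTable:
    """Class label -> synonym phrases, plus the shared prompt templates."""

    synonyms: dict[str, list[str]]
    templates: list[str] = field(default_factory=lambda: list(DEFAULT_TEMPLATES))

    def __post_init__(self):
        if not self.templates:
            raise ValueError("template list must be non-empty")
        for label, syns in self.synonyms.items():
            if not syns:
                raise ValueError(f"class {label!r} has no synonyms")
        for t in self.templates:
            if "{}" not in t:
                raise ValueError(f"template {t!r} has no placeholder")

    @property
    def classes(self) -> list[str]:
        return list(self.synonyms)

    @classmethod
    def brain(cls) -> "SynonymTable":
        return cls({k: list(v) for k, v in BRAIN_SYNONYMS.items()})

    @classmethod
    def organs(cls) -> "SynonymTable":
        return cls({k: list(v) for k, v in ORGAN_SYNONYMS.items()})

    @classmethod
    def from_config(cls, cfg: dict) -> "SynonymTable":
        """Load from a parsed config mapping: {"synonyms": {...}, "templates": [...]}"""
        return cls(synonyms={k: list(v) for k, v in cfg["synonyms"].items()},
                   templates=list(cfg.get("templates", DEFAULT_TEMPLATES)))

    @classmethod
    def from_yaml(cls, path) -> "SynonymTable":
        """Load a synonym table from a YAML file with the from_config layout."""
        import yaml

        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))


def build_prompt(label: str, table: SynonymTable,
                 rng: np.random.Generator) -> str:
    """Draw a (template, synonym) pair uniformly and substitute."""
    if label not in table.synonyms:
        raise KeyError(f"unknown class label {label!r}; "
                       f"known: {sorted(table.synonyms)}")
    template = table.templates[rng.integers(len(table.templates))]
    synonym = table.synonyms[label][rng.integers(len(table.synonyms[label]))]
    return template.format(synonym)


@dataclass
class TokenSequence:
    """Integer token ids padded/truncated to MAX_TOKENS, with attention flags."""

    ids: list[int]
    tokens: list[str]
    attention: list[int]   # 1 = real token, 0 = padding

    def __post_init__(self):
        if not (2 <= len(self.ids) <= MAX_TOKENS):
            raise ValueError("token sequence must hold 2..16 positions")
        if not (len(self.ids) == len(self.tokens) == len(self.attention)):
            raise ValueError("ids/tokens/attention lengths disagree")


_WORD_RE = re.compile(r"[a-z0-9]+")


def _token_id(token: str) -> int:
    """Stable 31-bit id from the token string (independent of PYTHONHASHSEED)."""
    if token == PAD:
        return 0
    digest = hashlib.sha256(token.encode()).digest()
    return (int.from_bytes(digest[:4], "big") & 0x7FFFFFFF) or 1


def tokenize(prompt: str) -> TokenSequence:
    """Lowercase, split on non-alphanumerics, wrap in [CLS]/[SEP], cap at 16."""
    if not prompt or not prompt.strip():
        raise ValueError("prompt must be a non-empty string")
    words = _WORD_RE.findall(prompt.lower())
    words = words[:MAX_TOKENS - 2]            # room for the two markers
    tokens = [CLS] + words + [SEP]
    attention = [1] * len(tokens)
    while len(tokens) < MAX_TOKENS:
        tokens.append(PAD)
        attention.append(0)
    return TokenSequence(ids=[_token_id(t) for t in tokens],
                         tokens=tokens, attention=attention)


@dataclass
class PromptEmbedding:
    """The pooled 768-dim semantic vector v_t with its provenance."""

    vector: np.ndarray
    prompt_text: str
    embedder_id: str

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if self.vector.shape != (EMBED_DIM,):
            raise ValueError(f"embedding must be {EMBED_DIM}-dim, "
                             f"got {self.vector.shape}")
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("embedding contains non-finite values")


class HashEmbedder:
    """Deterministic fallback token embedder.

    Each token's 768-vector is standard normal, seeded from a salted
    SHA-256 of the token string, then scaled by 1/sqrt(768) so pooled
    vectors have O(1) norm.  No trainable state: frozen by construction.
    """

    id = "hash-768-v1"

    def __init__(self, salt: str = "promptseg"):
        self.salt = salt
        self._cache: dict[str, np.ndarray] = {}

    def __call__(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            digest = hashlib.sha256(f"{self.salt}|{token}".encode()).digest()
            seed = int.from_bytes(digest[:8], "big") % (2 ** 31)
            vec = np.random.default_rng(seed).standard_normal(EMBED_DIM)
            vec /= np.sqrt(EMBED_DIM)
            self._cache[token] = vec
        return vec


def embed(tokens: TokenSequence, embedder=None,
          prompt_text: str = "") -> PromptEmbedding:
    """Mean-pool per-token vectors over non-padding positions -> v_t.

    The markers [CLS]/[SEP] participate in the mean ("all token
    embeddings"); padding positions do not.
    """
    embedder = embedder if embedder is not None else HashEmbedder()
    vecs = []
    for tok, flag in zip(tokens.tokens, tokens.attention):
        if not flag:
            continue
        v = np.asarray(embedder(tok), dtype=np.float64)
        if v.shape != (EMBED_DIM,):
            raise ValueError(
                f"embedder {getattr(embedder, 'id', embedder)!r} returned "
                f"shape {v.shape}, expected ({EMBED_DIM},)")
        vecs.append(v)
    v_t = np.mean(vecs, axis=0)
    return PromptEmbedding(vector=v_t, prompt_text=prompt_text,
                           embedder_id=getattr(embedder, "id", "custom"))


def embed_prompt(prompt: str, embedder=None) -> PromptEmbedding:
    """Convenience: tokenize then embed."""
    return embed(tokenize(prompt), embedder, prompt_text=prompt)
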