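"""Tokenisation of heterogeneous per-patient records.

Wide clinical extractions mix categorical, continuous, free-text and
missing fields with no fixed schema. Each field is converted to a single
token by concatenating the variable name with a canonical value string:

* categorical  -> ``GCSTotalScore_04`` (numeric values zero-padded to
  width 2 for stable lexicographic behaviour);
* continuous   -> ``SystolicBloodPressure_BIN17``, where the bin index
  comes from 20 quantile bins learned on the training set (out-of-range
  test values clamp to the edge bins so no new tokens appear at test time);
* free text    -> ``InjuryDescription_skullfracture`` (lower-cased,
  special characters and spaces stripped);
* missing      -> ``PriorMedications_NA``.

A patient's representation is their *set* of unique tokens. The trained
vocabulary indexes every distinct training token, reserving index 0 for an
unrecognised-token placeholder that absorbs anything first seen at test
time. Tokenisation is a pure function of (record, config, bin edges).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

UNRECOGNISED = "<unrecognised>"
_TEXT_STRIP = re.compile(r"[^a-z0-9]")


@dataclass(frozen=True)
class TokenizerConfig:
    """Tokenisation rules: bin count, missing-token suffix, per-variable kinds."""

    kind_map: dict[str, str] = field(default_factory=dict)
    n_bins: int = 20
    missing_suffix: str = "NA"

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")


def normalise_text(text: str) -> str:
    """Lower-case and strip spaces/special characters from free text."""
    return _TEXT_STRIP.sub("", str(text).lower())


def format_categorical(value) -> str:
    """Canonical string for a categorical value; numerics zero-padded to width 2."""
    if isinstance(value, (bool, np.bool_)):
        return f"{int(value):02d}"
    if isinstance(value, (int, np.integer)):
        return f"{int(value):02d}"
    if isinstance(value, (float, np.floating)):
        if float(value).is_integer():
            return f"{int(value):02d}"
        return normalise_text(repr(value))
    return normalise_text(value)


def learn_quantile_bins(values, n_bins: int = 20) -> np.ndarray:
    """Interior quantile bin edges learned from training values.

    Returns up to ``n_bins - 1`` interior edges at empirical quantiles;
    duplicate quantiles from heavy ties are merged (fewer effective bins,
    with a warning). All-missing input is an error.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("cannot learn bins: all values missing")
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    edges = np.unique(np.quantile(vals, qs))
    if len(edges) < n_bins - 1:
        warnings.warn(
            f"ties reduce effective bins from {n_bins} to {len(edges) + 1}",
            UserWarning, stacklevel=2)
    return edges


def assign_bin(value: float, edges: np.ndarray) -> int:
    """1-based bin index; values beyond the training range clamp to edge bins."""
    return int(np.searchsorted(edges, value, side="right")) + 1


@dataclass(frozen=True)
class TokenSequence:
    """A patient's sorted unique tokens, optionally encoded under a vocabulary."""

    patient_id: str
    tokens: tuple[str, ...]
    indices: tuple[int, ...] = ()

    def __post_init__(self):
        if not self.tokens:
            raise ValueError("token sequence must be non-empty")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("token sequence contains duplicates")


def tokenize_record(record: dict, config: TokenizerConfig,
                    bin_edges: dict[str, np.ndarray]) -> TokenSequence:
    """Convert one raw record into its unique token set."""
    fields = record["fields"]
    if not fields:
        raise ValueError("record has no fields")
    tokens = set()
    for name, value in fields.items():
        if value is None or (isinstance(value, float) and np.isnan(value)):
            tokens.add(f"{name}_{config.missing_suffix}")
            continue
        kind = config.kind_map.get(name, "categorical")
        if kind == "continuous":
            edges = bin_edges.get(name)
            if edges is None or len(edges) == 0:
                tokens.add(f"{name}_BIN1")
            else:
                tokens.add(f"{name}_BIN{assign_bin(float(value), edges)}")
        elif kind == "text":
            tokens.add(f"{name}_{normalise_text(value)}")
        else:
            tokens.add(f"{name}_{format_categorical(value)}")
    return TokenSequence(patient_id=record["patient_id"],
                         tokens=tuple(sorted(tokens)))


class TokenVocabulary:
    """Ordered token -> index map with the placeholder at index 0."""

    def __init__(self, tokens):
        self.index = {UNRECOGNISED: 0}
        for tok in sorted(set(tokens)):
            self.index[tok] = len(self.index)

    def __len__(self) -> int:
        return len(self.index)

    def encode(self, tokens) -> tuple[int, ...]:
        """Indices for a token set; unseen tokens map to the placeholder 0."""
        return tuple(self.index.get(t, 0) for t in tokens)

    def to_json(self, path, bin_edges: dict[str, np.ndarray] | None = None) -> None:
        payload = {"tokens": list(self.index.keys())}
        if bin_edges is not None:
            payload["bin_edges"] = {k: list(map(float, v))
                                    for k, v in bin_edges.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> tuple["TokenVocabulary", dict[str, np.ndarray]]:
        with open(path) as fh:
            payload = json.load(fh)
        vocab = cls.__new__(cls)
        vocab.index = {tok: i for i, tok in enumerate(payload["tokens"])}
        edges = {k: np.asarray(v) for k, v in payload.get("bin_edges", {}).items()}
        return vocab, edges


def build_vocabulary(sequences) -> TokenVocabulary:
    """Index all distinct tokens of the training sequences (placeholder at 0)."""
    seqs = list(sequences)
    if not seqs:
        raise ValueError("need at least one training token sequence")
    return TokenVocabulary(t for s in seqs for t in s.tokens)


class RecordTokenizer(BaseEstimator, TransformerMixin):
    """Learn bin edges and a vocabulary from training records; encode any records.

    ``fit`` learns per-variable quantile bin edges from the training
    records' continuous values and builds the token vocabulary from the
    training token sequences only. ``transform`` tokenises records and
    encodes them under the trained vocabulary (unseen tokens -> index 0).
    """

    def __init__(self, kind_map: dict[str, str], n_bins: int = 20,
                 missing_suffix: str = "NA"):
        self.kind_map = kind_map
        self.n_bins = n_bins
        self.missing_suffix = missing_suffix

    @property
    def config(self) -> TokenizerConfig:
        return TokenizerConfig(kind_map=self.kind_map, n_bins=self.n_bins,
                               missing_suffix=self.missing_suffix)

    def fit(self, records, y=None):
        cont_values: dict[str, list[float]] = {}
        for rec in records:
            for name, value in rec["fields"].items():
                if (self.kind_map.get(name) == "continuous" and value is not None
                        and not (isinstance(value, float) and np.isnan(value))):
                    cont_values.setdefault(name, []).append(float(value))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            self.bin_edges_ = {name: learn_quantile_bins(vals, self.n_bins)
                               for name, vals in cont_values.items()}
        train_seqs = [tokenize_record(r, self.config, self.bin_edges_)
                      for r in records]
        self.vocabulary_ = build_vocabulary(train_seqs)
        return self

    def transform(self, records, y=None) -> list[TokenSequence]:
        check_is_fitted(self, "vocabulary_")
        out = []
        for rec in records:
            seq = tokenize_record(rec, self.config, self.bin_edges_)
            out.append(TokenSequence(seq.patient_id, seq.tokens,
                                     self.vocabulary_.encode(seq.tokens)))
        return out


def write_sequences_jsonl(sequences, path) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(json.dumps({"patient_id": s.patient_id,
                                 "tokens": list(s.tokens),
                                 "indices": list(s.indices)}) + "\n")
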