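"""Promoter-expression tables: parsing, filtering/standardisation, encoding.

The assay construct is a 110-nt promoter: a fixed 17-nt 5' flank, a ~80-nt
variable insert, and a fixed 13-nt 3' flank.  Raw libraries contain length
variants and unknown bases (N); the preprocessing here keeps sequences of
length 110±3 with at most three N, pads short survivors with N at the 3' end
and truncates long ones at the 3' end, so every record downstream is exactly
110 nt.

Five encoding schemes are supported.  All place A,C,G,T one-hot in channels
1-4; they differ in how N and per-record measurement support are represented:

==============  ========  ====================================================
scheme          channels  extras
==============  ========  ====================================================
onehot          4         N -> [0,0,0,0]
onehotWithP     4         N -> [0.25,0.25,0.25,0.25] (uniform base probability)
onehotWithN     5         binary channel 5 marks N positions
onehotWithInt   5         channel 5 = 1/sqrt(support) (1 if missing), all pos.
onehotWithBoth  6         N channel plus support/uncertainty channel
==============  ========  ====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SEQ_LEN = 110
FLANK5_LEN = 17
FLANK3_LEN = 13
VARIABLE_REGION = (18, 97)  # 1-based inclusive positions of the insert
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
ENCODING_CHANNELS = {
    "onehot": 4,
    "onehotWithP": 4,
    "onehotWithN": 5,
    "onehotWithInt": 5,
    "onehotWithBoth": 6,
}
ENCODINGS = tuple(ENCODING_CHANNELS)


@dataclass
class PromoterRecord:
    """One promoter with its observed (or simulated) expression."""
    sequence: str
    expression: float
    support: float | None = None


@dataclass
class EncodingScheme:
    name: str
    channels: int = 0

    def __post_init__(self) -> None:
        if self.name not in ENCODING_CHANNELS:
            raise ValueError(
                f"unknown encoding {self.name!r}; choose from {ENCODINGS}")
        expected = ENCODING_CHANNELS[self.name]
        if self.channels == 0:
            self.channels = expected
        elif self.channels != expected:
            raise ValueError(
                f"encoding {self.name} has {expected} channels, "
                f"not {self.channels}")


@dataclass
class EncodedBatch:
    """Encoded sequences as a (n, 110, 1, channels) tensor; channels 1-4 are
    A,C,G,T in that order."""
    values: np.ndarray
    scheme: EncodingScheme

    def __post_init__(self) -> None:
        if self.values.ndim != 4 or self.values.shape[2] != 1 \
                or self.values.shape[3] != self.scheme.channels:
            raise ValueError(
                f"expected shape (n, L, 1, {self.scheme.channels}), "
                f"got {self.values.shape}")

    def __len__(self) -> int:
        return self.values.shape[0]

    def to_ncl(self) -> np.ndarray:
        """Channel-major view (n, channels, L) used by the network."""
        return np.ascontiguousarray(self.values[:, :, 0, :].transpose(0, 2, 1))


@dataclass
class FilterReport:
    n_in: int = 0
    n_discarded_length: int = 0
    n_discarded_n: int = 0
    n_kept: int = 0

    def __post_init__(self) -> None:
        assert self.n_in == (self.n_kept + self.n_discarded_length
                             + self.n_discarded_n)


# --------------------------------------------------------------------------- #
# tables

def read_table(path) -> list[PromoterRecord]:
    """Read a headerless TSV of sequence<TAB>expression[<TAB>support]."""
    records: list[PromoterRecord] = []
    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ValueError(
                    f"{path}: line {ln}: expected 2 or 3 tab-separated "
                    f"columns, got {len(parts)}")
            seq = parts[0].upper()
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(
                    f"{path}: line {ln}: invalid sequence characters "
                    f"{sorted(bad)}")
            try:
                expr = float(parts[1])
            except ValueError as err:
                raise ValueError(
                    f"{path}: line {ln}: non-numeric expression "
                    f"{parts[1]!r}") from err
            support = None
            if len(parts) == 3:
                try:
                    support = float(parts[2])
                except ValueError as err:
                    raise ValueError(
                        f"{path}: line {ln}: non-numeric support "
                        f"{parts[2]!r}") from err
            records.append(PromoterRecord(seq, expr, support))
    return records


def write_table(records: list[PromoterRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            cols = [rec.sequence, repr(rec.expression)]
            if rec.support is not None:
                cols.append(repr(rec.support))
            fh.write("\t".join(cols) + "\n")


# --------------------------------------------------------------------------- #
# filtering / standardisation

def filter_standardize(records: list[PromoterRecord], target_len: int = SEQ_LEN,
                       tol: int = 3, max_n: int = 3,
                       ) -> tuple[list[PromoterRecord], FilterReport]:
    """Apply the library filters and standardise survivors to ``target_len``.

    The length filter runs first (keep len in [target_len-tol, target_len+tol]),
    then the N filter on survivors (at most ``max_n`` N, counted before
    padding).  Short survivors are padded with N at the 3' end; long ones are
    truncated at the 3' end.

    The N count excludes the trailing run of N, which is indistinguishable
    from 3'-end padding; this makes the operation idempotent (padding a kept
    record never disqualifies it on a second pass).
    """
    kept: list[PromoterRecord] = []
    n_len = n_n = 0
    for rec in records:
        L = len(rec.sequence)
        if not target_len - tol <= L <= target_len + tol:
            n_len += 1
            continue
        if rec.sequence.rstrip("N").count("N") > max_n:
            n_n += 1
            continue
        seq = rec.sequence
        if L < target_len:
            seq = seq + "N" * (target_len - L)
        elif L > target_len:
            seq = seq[:target_len]
        kept.append(PromoterRecord(seq, rec.expression, rec.support))
    report = FilterReport(n_in=len(records), n_discarded_length=n_len,
                          n_discarded_n=n_n, n_kept=len(kept))
    return kept, report


# --------------------------------------------------------------------------- #
# encoding

def encode_batch(records: list[PromoterRecord],
                 scheme: EncodingScheme | str) -> EncodedBatch:
    """Encode standardised (length-110) records as (n, 110, 1, c)."""
    if isinstance(scheme, str):
        scheme = EncodingScheme(scheme)
    n = len(records)
    c = scheme.channels
    values = np.zeros((n, SEQ_LEN, 1, c), dtype=np.float32)
    for i, rec in enumerate(records):
        if len(rec.sequence) != SEQ_LEN:
            raise ValueError(
                f"record {i}: sequence length {len(rec.sequence)} != "
                f"{SEQ_LEN}; run filter_standardize first")
        for p, base in enumerate(rec.sequence):
            if base == "N":
                if scheme.name == "onehotWithP":
                    values[i, p, 0, :4] = 0.25
                elif scheme.name in ("onehotWithN", "onehotWithBoth"):
                    values[i, p, 0, 4] = 1.0
            else:
                values[i, p, 0, BASE_INDEX[base]] = 1.0
        if scheme.name in ("onehotWithInt", "onehotWithBoth"):
            ch = 4 if scheme.name == "onehotWithInt" else 5
            support = rec.support
            unc = 1.0 if support is None or support <= 0 \
                else 1.0 / np.sqrt(support)
            values[i, :, 0, ch] = unc
    return EncodedBatch(values=values, scheme=scheme)


def decode_batch(batch: EncodedBatch) -> list[str]:
    """Invert :func:`encode_batch`; error on slices no scheme can produce."""
    scheme = batch.scheme
    seqs: list[str] = []
    for i in range(len(batch)):
        chars: list[str] = []
        for p in range(batch.values.shape[1]):
            four = batch.values[i, p, 0, :4]
            if scheme.name == "onehotWithP" and np.allclose(four, 0.25):
                chars.append("N")
                continue
            if scheme.name in ("onehotWithN", "onehotWithBoth") \
                    and batch.values[i, p, 0, 4] == 1.0:
                if np.any(four != 0):
                    raise ValueError(
                        f"sequence {i} position {p + 1}: N channel set "
                        "alongside a base channel")
                chars.append("N")
                continue
            if np.all(four == 0):
                if scheme.name in ("onehot", "onehotWithInt"):
                    chars.append("N")
                    continue
                raise ValueError(
                    f"sequence {i} position {p + 1}: all-zero base channels "
                    f"invalid under {scheme.name}")
            hot = np.flatnonzero(four == 1.0)
            if hot.size != 1 or not np.isclose(four.sum(), 1.0):
                raise ValueError(
                    f"sequence {i} position {p + 1}: ambiguous base slice "
                    f"{four.tolist()}")
            chars.append(BASES[hot[0]])
        seqs.append("".join(chars))
    return seqs
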