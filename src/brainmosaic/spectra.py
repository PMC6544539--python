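"""Mutational spectra and signature correlation.

Single-nucleotide substitutions are represented in the pyrimidine-collapsed
convention: a substitution whose reference base is a purine is recorded by
its reverse complement, so every event falls into one of six classes
(C>A, C>G, C>T, T>A, T>C, T>G).  With the two flanking reference bases this
expands to the standard 96 trinucleotide channels.  Spectra are correlated
against reference signature matrices (96 channels x K signatures) with the
Pearson product-moment statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SIX_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
#: 96-channel layout: class-major, then 5' flank A/C/G/T, then 3' flank.
CHANNELS_96 = tuple(
    f"{f5}[{cls}]{f3}" for cls in SIX_CLASSES for f5 in BASES for f3 in BASES
)
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _check_base(b: str, what: str) -> str:
    b = str(b).upper()
    if b not in BASES:
        raise ValueError(f"{what} must be one of A/C/G/T, got {b!r}")
    return b


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def classify_substitution(ref: str, alt: str) -> tuple[str, str]:
    """Map an (ref, alt) substitution to its pyrimidine-collapsed class.

    Returns ``(six_class, kind)`` where kind is ``"transition"`` or
    ``"transversion"``.
    """
    ref = _check_base(ref, "ref")
    alt = _check_base(alt, "alt")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    kind = "transition" if frozenset((ref, alt)) in _TRANSITIONS else "transversion"
    if ref in ("G", "A"):  # collapse to pyrimidine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}", kind


def collapse_context(ref: str, alt: str, context: str) -> tuple[str, str, str]:
    """Collapse (ref, alt, trinucleotide context) to pyrimidine orientation.

    The whole context is reverse-complemented when the reference base is a
    purine, so flanks swap sides as well as complementing.
    """
    ref = _check_base(ref, "ref")
    alt = _check_base(alt, "alt")
    context = str(context).upper()
    if len(context) != 3 or any(b not in BASES for b in context):
        raise ValueError(f"context must be a trinucleotide over A/C/G/T, got {context!r}")
    if context[1] != ref:
        raise ValueError(f"context middle base {context[1]!r} does not match ref {ref!r}")
    if ref in ("G", "A"):
        context = reverse_complement(context)
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return ref, alt, context


def channel_name(ref: str, alt: str, context: str) -> str:
    ref, alt, context = collapse_context(ref, alt, context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


@dataclass
class MutationSpectrum:
    """Substitution counts in 6-class and (optionally) 96-channel form."""

    six_class: pd.Series
    channels96: pd.Series | None
    n_variants: int
    n_transitions: int
    n_transversions: int

    def normalized_channels(self) -> pd.Series:
        if self.channels96 is None:
            raise ValueError("no 96-channel representation (contexts unavailable)")
        total = self.channels96.sum()
        if total == 0:
            raise ValueError("empty spectrum cannot be normalized")
        return self.channels96 / total

    def normalized_six(self) -> pd.Series:
        total = self.six_class.sum()
        if total == 0:
            raise ValueError("empty spectrum cannot be normalized")
        return self.six_class / total


def build_spectrum(
    variants: Iterable[tuple[str, str] | tuple[str, str, str]]
) -> MutationSpectrum:
    """Tally substitutions into the 6-class and, when every record carries a
    trinucleotide context, the 96-channel spectrum.

    ``variants`` yields ``(ref, alt)`` or ``(ref, alt, context)`` tuples.
    Mixing records with and without context is rejected.
    """
    six = pd.Series(0, index=list(SIX_CLASSES), dtype=int)
    chan = pd.Series(0, index=list(CHANNELS_96), dtype=int)
    n = n_ti = n_tv = 0
    have_context = None
    for i, rec in enumerate(variants):
        if len(rec) == 3 and rec[2] is not None and not (
            isinstance(rec[2], float) and np.isnan(rec[2])
        ):
            with_ctx = True
        else:
            with_ctx = False
        if have_context is None:
            have_context = with_ctx
        elif have_context != with_ctx:
            raise ValueError(f"record {i}: mixed presence/absence of contexts")
        ref, alt = rec[0], rec[1]
        cls, kind = classify_substitution(ref, alt)
        six[cls] += 1
        if with_ctx:
            try:
                chan[channel_name(ref, alt, rec[2])] += 1
            except ValueError as exc:
                raise ValueError(f"record {i} ({ref}>{alt}, {rec[2]}): {exc}") from exc
        n += 1
        if kind == "transition":
            n_ti += 1
        else:
            n_tv += 1
    return MutationSpectrum(
        six_class=six,
        channels96=chan if have_context else None,
        n_variants=n,
        n_transitions=n_ti,
        n_transversions=n_tv,
    )


def signature_correlation(
    spectrum: MutationSpectrum | pd.Series, signatures: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of a 96-channel spectrum against each signature.

    ``signatures`` is a 96 x K frame indexed by channel names with one
    column per signature.  Returns a frame with columns ``r``, ``r2``,
    ``p`` (two-sided, from the t transform with 94 degrees of freedom)
    sorted by ``r2`` descending.  Pearson r is scale invariant, so raw
    counts and normalized frequencies give identical results.
    """
    if isinstance(spectrum, MutationSpectrum):
        vec = spectrum.normalized_channels()
    else:
        vec = spectrum
    missing = set(vec.index) - set(signatures.index)
    if missing:
        raise ValueError(f"signature matrix is missing channels: {sorted(missing)[:5]} ...")
    sig = signatures.loc[vec.index]
    x = vec.to_numpy(dtype=float)
    rows = []
    for label in sig.columns:
        y = sig[label].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((label, np.nan, np.nan, np.nan))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((label, r, r * r, p))
    out = pd.DataFrame(rows, columns=["signature", "r", "r2", "p"])
    return out.sort_values("r2", ascending=False, ignore_index=True)


def cpg_fraction(
    variants: Iterable[tuple[str, str, str]]
) -> tuple[int, int, float]:
    """Fraction of C>T-class variants occurring at CpG sites.

    A variant is at a CpG when, in pyrimidine orientation, the mutated C is
    immediately followed by G (so a G>A variant with a 5' C on the given
    strand counts after collapse).  Returns ``(n_cpg, n_ct, fraction)``;
    the fraction is NaN when there are no C>T-class variants.
    """
    n_ct = n_cpg = 0
    for ref, alt, context in variants:
        cref, calt, cctx = collapse_context(ref, alt, context)
        if (cref, calt) == ("C", "T"):
            n_ct += 1
            if cctx[2] == "G":
                n_cpg += 1
    return n_cpg, n_ct, (n_cpg / n_ct if n_ct else float("nan"))


def read_signature_matrix(path) -> pd.DataFrame:
    """Read a TSV signature matrix: first column channel names (e.g.
    ``A[C>T]G``), remaining columns one signature each; columns must each
    sum to 1 within 1e-6."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _validate_signature_matrix(df)
    return df


def _validate_signature_matrix(df: pd.DataFrame) -> None:
    if set(df.index) != set(CHANNELS_96):
        raise ValueError("signature matrix must be indexed by the 96 channel names")
    if (df.to_numpy() < 0).any():
        raise ValueError("signature entries must be non-negative")
    sums = df.sum(axis=0)
    bad = sums[(sums - 1).abs() > 1e-6]
    if len(bad):
        raise ValueError(f"signature columns must sum to 1: {list(bad.index)}")


def random_signature_matrix(k: int, seed: int, concentration: float = 0.5) -> pd.DataFrame:
    """Synthetic signature matrix (Dirichlet columns) for tests and demos."""
    rng = np.random.default_rng(seed)
    cols = {
        f"Signature.{i + 1}": rng.dirichlet(np.full(96, concentration))
        for i in range(k)
    }
    return pd.DataFrame(cols, index=list(CHANNELS_96))
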