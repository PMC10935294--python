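"""Synthetic-data generators with known ground truth for every pipeline stage.

Every generator takes an explicit integer seed, uses its own
``numpy.random.Generator`` (no global state), and returns its ground truth
alongside the data, so the digestion engine, the QSAR models, the
dose-response fit and the inhibition-kinetics classifier can all be exercised
as parameter-recovery problems without any wet-lab input.

Default parameter scales mirror a typical ACE-inhibition study: IC50s in the
0.5–500 µM range, the substrate grid {0.5, 1, 2, 4, 5} mM of an HHL assay,
and inhibitor levels {0, 0.2, 0.5} mg/mL.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np

from .proteolysis import (
    STANDARD_AA,
    CleavageRule,
    Peptide,
    ProteinRecord,
    cleavage_sites,
    digest,
    load_rules,
)
from .qsar import IC50_ADMISSION_UM, QsarDataset
from .kinetics import DoseResponse, KineticSeries, _log_logistic

_ALPHABET = "".join(sorted(STANDARD_AA))

DEFAULT_SUBSTRATE_MM = (0.5, 1.0, 2.0, 4.0, 5.0)
DEFAULT_INHIBITOR_CONCS = (0.0, 0.2, 0.5)


# ---------------------------------------------------------------------------
# Proteins with plantable cleavage products
# ---------------------------------------------------------------------------

def gen_protein(seed: int, length: int = 200,
                planted: Sequence[str] = (),
                separator_residue: str = "K",
                rules: Sequence[CleavageRule] | None = None
                ) -> tuple[ProteinRecord, dict[str, tuple[int, int]]]:
    """A random protein whose digest releases every planted peptide intact.

    Planted peptides are embedded between ``separator_residue`` spacers inside
    a random background; the construction is then *verified* by digesting with
    ``rules`` (default: packaged trypsin).  A planted peptide that carries an
    internal cleavage site, or whose termini do not cleave in context, raises
    a ``ValueError`` naming the offending bond.

    Returns the protein and a truth map {peptide → (start, end)} (1-based
    inclusive coordinates).
    """
    rng = np.random.default_rng(seed)
    if rules is None:
        rules = load_rules(enzymes=["trypsin"])
    if separator_residue not in STANDARD_AA:
        raise ValueError(f"separator {separator_residue!r} is not a standard residue")

    min_len = sum(len(p) for p in planted) + 2 * max(len(planted), 1)
    if length < min_len:
        raise ValueError(f"length {length} too small for the planted peptides "
                         f"(need ≥ {min_len})")

    n_gaps = len(planted) + 1
    budget = length - sum(len(p) for p in planted) - 2 * len(planted)
    gap_lengths = _split_budget(rng, budget, n_gaps)

    parts: list[str] = []
    truth: dict[str, tuple[int, int]] = {}
    pos = 0
    for pep, gap in zip(planted, gap_lengths):
        bg = _random_background(rng, gap)
        parts.extend([bg, separator_residue])
        pos += gap + 1
        truth[pep] = (pos + 1, pos + len(pep))
        parts.extend([pep, separator_residue])
        pos += len(pep) + 1
    parts.append(_random_background(rng, gap_lengths[-1]))
    protein = ProteinRecord(f"synthetic_{seed}", "".join(parts))

    _verify_planted(protein, truth, rules)
    return protein, truth


def _random_background(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_ALPHABET), size=n)) if n > 0 else ""


def _split_budget(rng: np.random.Generator, budget: int, parts: int) -> list[int]:
    cuts = np.sort(rng.integers(0, budget + 1, size=parts - 1)) if parts > 1 else []
    bounds = [0, *cuts, budget]
    return [int(b - a) for a, b in zip(bounds[:-1], bounds[1:])]


def _verify_planted(protein: ProteinRecord, truth: dict[str, tuple[int, int]],
                    rules: Sequence[CleavageRule]) -> None:
    sites = cleavage_sites(protein, rules)
    for pep, (start, end) in truth.items():
        internal = [b for b in sites if start <= b < end]
        if internal:
            bond = internal[0]
            raise ValueError(
                f"planted peptide {pep!r} has an internal cleavage site at "
                f"bond {bond} ({protein.sequence[bond - 1]}|"
                f"{protein.sequence[bond]}) under the given rules"
            )
        if start > 1 and (start - 1) not in sites:
            raise ValueError(
                f"planted peptide {pep!r}: N-terminal boundary bond "
                f"{start - 1} is not cleaved under the given rules"
            )
        if end < len(protein) and end not in sites:
            raise ValueError(
                f"planted peptide {pep!r}: C-terminal boundary bond {end} is "
                f"not cleaved under the given rules (its last residue must "
                f"match a rule in context)"
            )


def random_plantable_peptide(rng: np.random.Generator, length: int) -> str:
    """A random peptide with no internal trypsin site that ends in K or R.

    The body avoids K/R (no internal cut) and P (which would block the cut
    after the preceding separator or residue); the terminal K/R makes the
    C-terminal boundary cleave under trypsin.
    """
    body_alphabet = [a for a in _ALPHABET if a not in "KRP"]
    body = "".join(rng.choice(body_alphabet, size=length - 1))
    return body + str(rng.choice(["K", "R"]))


# ---------------------------------------------------------------------------
# QSAR training sets
# ---------------------------------------------------------------------------

def gen_qsar_dataset(seed: int, n: int = 100, length: int = 6,
                     beta: np.ndarray | None = None,
                     intercept: float = 1.7, sigma: float = 0.2
                     ) -> tuple[QsarDataset, dict]:
    """Random peptides whose log10-IC50 is linear in their z-scale descriptors.

    ``log10 IC50 = intercept + x·beta + N(0, σ²)``; records at or above the
    15 mM admission bound are resampled.  When ``beta`` is omitted a random
    coefficient vector is drawn, scaled so that the systematic log-IC50
    spread is ≈ 0.7 (IC50s spanning roughly 0.5–500 µM around the default
    intercept of 1.7 = log10(50 µM)).

    Returns the dataset and the truth dict (beta, intercept, sigma, per-record
    noiseless log-IC50).
    """
    if n < 10:
        raise ValueError("need n ≥ 10")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    from .zscale import encode_peptide

    rng = np.random.default_rng(seed)
    p = 5 * length
    if beta is None:
        beta = rng.normal(0.0, 0.7 / (2.3 * np.sqrt(p)), size=p)
    beta = np.asarray(beta, float)
    if beta.shape != (p,):
        raise ValueError(f"beta must have length {p}")

    sequences: list[str] = []
    ic50: list[float] = []
    log_true: list[float] = []
    while len(sequences) < n:
        seq = "".join(rng.choice(list(_ALPHABET), size=length))
        mu = intercept + float(encode_peptide(seq) @ beta)
        val = mu + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
        if 10.0 ** val >= IC50_ADMISSION_UM:
            continue  # resample to respect the admission bound
        sequences.append(seq)
        ic50.append(10.0 ** val)
        log_true.append(mu)

    dataset = QsarDataset(tuple(sequences), np.array(ic50), length)
    truth = {
        "beta": beta,
        "intercept": intercept,
        "sigma": sigma,
        "log_ic50_true": np.array(log_true),
    }
    return dataset, truth


# ---------------------------------------------------------------------------
# Inhibition kinetics
# ---------------------------------------------------------------------------

_RATE_LAWS = {
    "competitive":
        lambda S, I, vmax, km, ki, alpha: vmax * S / (km * (1 + I / ki) + S),
    "non-competitive":
        lambda S, I, vmax, km, ki, alpha: vmax * S / ((km + S) * (1 + I / ki)),
    "uncompetitive":
        lambda S, I, vmax, km, ki, alpha: vmax * S / (km + S * (1 + I / ki)),
    "mixed":
        lambda S, I, vmax, km, ki, alpha:
            vmax * S / (km * (1 + I / ki) + S * (1 + I / (alpha * ki))),
}


def gen_kinetics(seed: int, mode: str = "competitive",
                 vmax: float = 2.0, km: float = 1.0, ki: float = 0.2,
                 alpha: float = 2.0,
                 inhibitor_concs: Sequence[float] = DEFAULT_INHIBITOR_CONCS,
                 substrate_concs: Sequence[float] = DEFAULT_SUBSTRATE_MM,
                 sigma: float = 0.0) -> tuple[list[KineticSeries], dict]:
    """Michaelis–Menten velocity series under a known inhibition mechanism.

    Velocities follow the mechanism's rate law with multiplicative Gaussian
    noise ``v · (1 + N(0, σ²))``.  The first inhibitor level (typically 0) is
    the control.  Truth records the generating parameters and the apparent
    (Km, Vmax) per level implied by the mechanism.
    """
    if mode not in _RATE_LAWS:
        raise ValueError(f"mode must be one of {sorted(_RATE_LAWS)}")
    if min(vmax, km, ki, alpha) <= 0:
        raise ValueError("kinetic parameters must be positive")
    rng = np.random.default_rng(seed)
    law = _RATE_LAWS[mode]
    S = np.asarray(substrate_concs, float)

    series: list[KineticSeries] = []
    apparent: list[dict] = []
    for I in inhibitor_concs:
        v = law(S, I, vmax, km, ki, alpha)
        if sigma > 0:
            v = v * (1.0 + rng.normal(0.0, sigma, size=S.shape))
        series.append(KineticSeries(float(I), S.copy(), v))
        apparent.append(_apparent_params(mode, I, vmax, km, ki, alpha))
    truth = {
        "mode": mode, "vmax": vmax, "km": km, "ki": ki, "alpha": alpha,
        "sigma": sigma, "apparent": apparent,
    }
    return series, truth


def _apparent_params(mode: str, I: float, vmax: float, km: float,
                     ki: float, alpha: float) -> dict:
    if mode == "competitive":
        return {"I": I, "km": km * (1 + I / ki), "vmax": vmax}
    if mode == "non-competitive":
        return {"I": I, "km": km, "vmax": vmax / (1 + I / ki)}
    if mode == "uncompetitive":
        f = 1 + I / ki
        return {"I": I, "km": km / f, "vmax": vmax / f}
    f1, f2 = 1 + I / ki, 1 + I / (alpha * ki)
    return {"I": I, "km": km * f1 / f2, "vmax": vmax / f2}


# ---------------------------------------------------------------------------
# Dose-response curves
# ---------------------------------------------------------------------------

def gen_dose_response(seed: int, ic50: float = 5.0, hill: float = 1.0,
                      concs: Sequence[float] | None = None,
                      sigma: float = 0.0
                      ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Log-logistic dose-response points with additive Gaussian noise (% points).

    Default concentrations form a two-fold geometric series spanning 1/8× to
    8× the true IC50.  Returns (concentrations, inhibition %, truth).
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    rng = np.random.default_rng(seed)
    if concs is None:
        concs = ic50 * 2.0 ** np.arange(-3, 4)
    c = np.asarray(concs, float)
    y = _log_logistic(c, ic50, hill)
    if sigma > 0:
        y = np.clip(y + rng.normal(0.0, sigma, size=c.shape), -10.0, 110.0)
    return c, y, {"ic50": ic50, "hill": hill, "sigma": sigma}
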