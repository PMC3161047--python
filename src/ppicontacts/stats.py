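"""Residue propensities and ASA-normalized contact-preference statistics.

Two summary statistics are derived over a set of interfaces:

* Environment-dependent residue propensity.  With F_i the count of residue
  type i over all residues and F_ei the count within structural environment
  e, the background frequency is B_i = F_i / Σ_k F_k, the environment
  frequency is E_ei = F_ei / Σ_k F_ek and the normalized propensity is
  R_ei = E_ei / B_i (> 1 means enrichment in that environment).

* Contact pairing preference.  C_ij counts unordered inter-chain residue
  pairs of types (i, j) in contact; U_i counts distinct residues of type i
  engaged in contacts.  The observed pair frequency is P_ij = C_ij / Σ C
  (over unordered pairs), the individual frequency W_i = U_i / Σ U is
  ASA-normalized to Ŵ_i ∝ U_i · asa_i, and the preference is the log-odds
  L(i,j) = ln( P_ij / (κ · E_ij) ) with E_ij = 2·Ŵ_i·Ŵ_j off-diagonal and
  Ŵ_i² on the diagonal (the symmetric-multinomial expected model) and κ
  normalizing the expected matrix to unit total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .asa import ENVIRONMENTS, ResidueEnvironment

logger = logging.getLogger(__name__)

RESIDUE_TYPES = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()


@dataclass
class PropensityTable:
    counts: pd.DataFrame        # F_ei, environments x residue types
    background: pd.Series       # B_i
    env_frequency: pd.DataFrame  # E_ei
    propensity: pd.DataFrame    # R_ei (NaN where the type is absent overall)


@dataclass
class ContactMatrix:
    counts: pd.DataFrame          # C_ij, symmetric
    engaged: pd.Series            # U_i
    pair_frequency: pd.DataFrame | None = None  # P_ij over unordered pairs
    individual_frequency: pd.Series | None = None  # W_i
    asa_weighted_frequency: pd.Series | None = None  # Ŵ_i
    log_odds: pd.DataFrame | None = None  # L(i, j)


def residue_propensities(
    envs: list[ResidueEnvironment] | list[tuple[str, str]]
) -> PropensityTable:
    """Propensity table from per-residue environment assignments.

    Accepts either :class:`ResidueEnvironment` objects or bare
    ``(res_name, environment)`` tuples.  All residues of the included
    complexes — not just interface residues — form the background.
    """
    pairs = [
        (e.res.res_name, e.environment) if isinstance(e, ResidueEnvironment) else e
        for e in envs
    ]
    types = sorted({t for t, _ in pairs} | set(RESIDUE_TYPES))
    counts = pd.DataFrame(0, index=list(ENVIRONMENTS), columns=types, dtype=float)
    for res_name, env in pairs:
        counts.loc[env, res_name] += 1

    f_i = counts.sum(axis=0)
    total = f_i.sum()
    background = f_i / total if total else f_i
    env_totals = counts.sum(axis=1)
    env_frequency = counts.div(env_totals.replace(0, np.nan), axis=0).fillna(0.0)
    for env in ENVIRONMENTS:
        if env_totals[env] == 0:
            logger.warning("environment %r is empty; its frequencies are zero", env)
    propensity = env_frequency.div(background.replace(0, np.nan), axis=1)
    # types absent from the background are undefined (NaN), not zero
    return PropensityTable(counts, background, env_frequency, propensity)


def contact_counts(
    residue_pairs: list[tuple[str, str, tuple, tuple]]
) -> ContactMatrix:
    """Observed contact matrix from residue-level contacts.

    ``residue_pairs`` holds (res_name_i, res_name_j, residue_id_i,
    residue_id_j) for residue pairs with at least one non-proximal-only
    atom-pair flag; each unordered residue pair is counted once and U_i
    counts distinct contacting residues of type i.
    """
    types = sorted(
        set(RESIDUE_TYPES) | {t for t, _, _, _ in residue_pairs} | {t for _, t, _, _ in residue_pairs}
    )
    c = pd.DataFrame(0.0, index=types, columns=types)
    seen_pairs: set = set()
    engaged: dict[str, set] = {}
    for ti, tj, id_i, id_j in residue_pairs:
        key = frozenset(((ti, id_i), (tj, id_j)))
        if key in seen_pairs:
            continue
        seen_pairs.add(key)
        c.loc[ti, tj] += 1
        if ti != tj:
            c.loc[tj, ti] += 1  # keep C symmetric; diagonal pairs counted once
        engaged.setdefault(ti, set()).add(id_i)
        engaged.setdefault(tj, set()).add(id_j)
    u = pd.Series({t: len(engaged.get(t, ())) for t in types}, dtype=float)
    return ContactMatrix(counts=c, engaged=u)


def contact_preferences(m: ContactMatrix, asa_ref: pd.Series) -> ContactMatrix:
    """Fill the frequency and log-odds fields of a contact matrix.

    ``asa_ref`` maps residue type to its reference (tripeptide) ASA in Å²,
    used to down-weight the expected frequency of large residues.  Cells with
    zero observed or expected frequency are reported absent (NaN).
    """
    types = list(m.counts.index)
    c = m.counts.to_numpy()
    upper = np.triu(c)  # unordered pairs: i <= j
    n_pairs = upper.sum()
    if n_pairs == 0:
        raise ValueError("no observed contacts")
    p = np.full_like(c, np.nan)
    iu = np.triu_indices(len(types))
    p[iu] = upper[iu] / n_pairs
    p = np.where(np.isnan(p), p.T, p)  # mirror for symmetric presentation

    u = m.engaged.reindex(types).fillna(0.0)
    w = u / u.sum() if u.sum() else u
    asa = asa_ref.reindex(types)
    if asa.isna().any():
        missing = list(asa.index[asa.isna()])
        raise ValueError(f"no reference ASA for residue types {missing}")
    wh_raw = u * asa
    wh = (wh_raw / wh_raw.sum()).to_numpy()

    expected = 2.0 * np.outer(wh, wh)
    np.fill_diagonal(expected, wh**2)
    # over unordered pairs the expected matrix sums to (Σ Ŵ)² = 1; κ guards
    # against round-off and degenerate inputs
    kappa = np.triu(expected).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_odds = np.log(p / (expected / kappa))
    log_odds[~np.isfinite(log_odds)] = np.nan

    return ContactMatrix(
        counts=m.counts,
        engaged=m.engaged,
        pair_frequency=pd.DataFrame(p, index=types, columns=types),
        individual_frequency=w,
        asa_weighted_frequency=pd.Series(wh, index=types),
        log_odds=pd.DataFrame(log_odds, index=types, columns=types),
    )
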