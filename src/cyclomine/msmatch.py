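"""Charge-state deconvolution and mass matching of LC-MS peak lists.

Cyclotide-like signals are read straight off centroided peak tables: isotope
envelopes are grouped greedily per retention-time bin, the charge (2+ or 3+)
is taken from the ~1.00336/z isotope spacing, the neutral monoisotopic mass
is M = z*mz - z*proton from the lowest-mass envelope peak, and observations
are kept when M falls in the 2,700-3,300 Da cyclotide window.  Identity as a
true three-disulfide cyclotide is confirmed by the +348.18 Da reduction+
alkylation shift; predicted matures match an observation when the masses
agree within 0.40 Da; abundance is binned low/medium/high on the summed 3+
envelope intensity at 250 and 1,000 counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .masscalc import PROTON, MatureCandidate

__all__ = [
    "MatchParams",
    "IsotopeEnvelope",
    "NeutralObservation",
    "charge_from_spacing",
    "detect_envelopes",
    "deconvolute",
    "confirm_alkylation",
    "match_predicted",
    "abundance_level",
    "ISOTOPE_DELTA",
]

ISOTOPE_DELTA = 1.00336  # Da between isotopic peaks at z=1


@dataclass(frozen=True)
class MatchParams:
    mass_tol: float = 0.40  # Da, strict < when matching calc vs observed
    neutral_window: tuple[float, float] = (2700.0, 3300.0)
    mz_window: tuple[float, float] = (1000.0, 2000.0)
    alk_delta: float = 348.18
    # the alkylation check gets a wider tolerance than the match tolerance:
    # observed alkylated masses deviate more after two measurements
    alk_tol: float = 0.75
    spacing_tol: float = 0.05
    min_isotope_peaks: int = 3
    si_low: float = 250.0
    si_high: float = 1000.0
    charges: tuple[int, ...] = (3, 2)  # tried in this order
    rt_bin: float = 0.2  # minutes

    def __post_init__(self) -> None:
        if self.si_low >= self.si_high:
            raise ValueError("si_low must be < si_high")


@dataclass(frozen=True)
class IsotopeEnvelope:
    rt: float
    charge: int
    mono_mz: float
    peaks: tuple[tuple[float, float], ...]  # (mz, intensity)

    @property
    def summed_intensity(self) -> float:
        return sum(i for _, i in self.peaks)

    @property
    def neutral_mass(self) -> float:
        return self.charge * self.mono_mz - self.charge * PROTON


@dataclass
class NeutralObservation:
    observation_id: str
    M: float
    rt: float
    envelopes: tuple[IsotopeEnvelope, ...]
    SI: float  # summed intensity of the 3+ envelope peaks (0 if 2+ only)
    abundance: str = "low"
    alkylation_confirmed: str = "untested"  # yes | no | untested
    flags: tuple[str, ...] = ()


def charge_from_spacing(mean_spacing: float, params: MatchParams = MatchParams()) -> int | None:
    """Charge state implied by the mean isotopic-peak spacing, or None.

    z is the nearest integer to 1.00336/spacing if the spacing residual is
    within tolerance and z is one of the allowed charges (2 or 3: singly
    charged cyclotide ions are not observed in this m/z window and higher
    charges are not assigned).
    """
    if mean_spacing <= 0:
        raise ValueError("spacing must be positive")
    z = round(ISOTOPE_DELTA / mean_spacing)
    if z not in params.charges:
        return None
    if abs(mean_spacing - ISOTOPE_DELTA / z) > params.spacing_tol:
        return None
    return z


def _rt_bins(rts: np.ndarray, width: float) -> np.ndarray:
    return np.floor(rts / width).astype(int)


def detect_envelopes(
    peaks: pd.DataFrame, params: MatchParams = MatchParams()
) -> list[IsotopeEnvelope]:
    """Greedy isotope-envelope grouping per retention-time bin.

    Peaks outside the acquisition m/z window are dropped.  Within each rt
    bin, starting from the most intense unassigned peak, the envelope is
    extended left and right on the 1.00336/z grid (z=3 tried before z=2,
    tolerance ``spacing_tol`` per step); an envelope needs at least
    ``min_isotope_peaks`` members and each peak joins at most one envelope.
    The reported mono m/z is the leftmost accepted peak.
    """
    df = peaks[(peaks["mz"] >= params.mz_window[0]) & (peaks["mz"] <= params.mz_window[1])]
    out: list[IsotopeEnvelope] = []
    for _, group in df.groupby(_rt_bins(df["rt_min"].to_numpy(), params.rt_bin), sort=True):
        mzs = group["mz"].to_numpy()
        intens = group["intensity"].to_numpy()
        rts = group["rt_min"].to_numpy()
        order = np.argsort(-intens, kind="stable")
        assigned = np.zeros(len(group), dtype=bool)
        for seed in order:
            if assigned[seed]:
                continue
            best_members: list[int] | None = None
            best_z = None
            for z in params.charges:
                step = ISOTOPE_DELTA / z
                members = [seed]
                for direction in (+1, -1):
                    current = mzs[seed]
                    while True:
                        target = current + direction * step
                        cand = np.where(
                            (~assigned)
                            & (np.abs(mzs - target) <= params.spacing_tol)
                        )[0]
                        cand = [c for c in cand if c not in members]
                        if not len(cand):
                            break
                        pick = min(cand, key=lambda c: abs(mzs[c] - target))
                        members.append(pick)
                        current = mzs[pick]
                if len(members) >= params.min_isotope_peaks:
                    best_members, best_z = members, z
                    break
            if best_members is None:
                continue
            best_members = sorted(best_members, key=lambda i: mzs[i])
            assigned[best_members] = True
            out.append(
                IsotopeEnvelope(
                    rt=float(rts[best_members[0]]),
                    charge=best_z,
                    mono_mz=float(mzs[best_members[0]]),
                    peaks=tuple((float(mzs[i]), float(intens[i])) for i in best_members),
                )
            )
    out.sort(key=lambda e: (e.rt, e.mono_mz))
    return out


def deconvolute(
    envelopes: Sequence[IsotopeEnvelope],
    params: MatchParams = MatchParams(),
    apply_neutral_window: bool = True,
) -> list[NeutralObservation]:
    """Neutral-mass observations from charge-grouped envelopes.

    Envelopes whose neutral masses agree within the mass tolerance in the
    same rt bin merge into one observation (mass = intensity-weighted mean,
    reported rt from the strongest envelope).  Observations outside the
    cyclotide neutral-mass window are discarded.  SI sums the 3+ envelope
    peaks; observations supported only by 2+ keep SI = 0 and are flagged.
    """
    groups: dict[int, list[IsotopeEnvelope]] = {}
    for env in envelopes:
        groups.setdefault(int(env.rt // params.rt_bin), []).append(env)
    out: list[NeutralObservation] = []
    n = 0
    for _, envs in sorted(groups.items()):
        envs = sorted(envs, key=lambda e: (e.neutral_mass, -e.summed_intensity))
        used = [False] * len(envs)
        for i, env in enumerate(envs):
            if used[i]:
                continue
            cluster = [env]
            used[i] = True
            for j in range(i + 1, len(envs)):
                if used[j]:
                    continue
                if abs(envs[j].neutral_mass - env.neutral_mass) <= params.mass_tol:
                    cluster.append(envs[j])
                    used[j] = True
            weights = [e.summed_intensity for e in cluster]
            M = float(np.average([e.neutral_mass for e in cluster], weights=weights))
            if apply_neutral_window and not (
                params.neutral_window[0] <= M <= params.neutral_window[1]
            ):
                continue
            si = sum(e.summed_intensity for e in cluster if e.charge == 3)
            flags = () if any(e.charge == 3 for e in cluster) else ("no_3plus_support",)
            strongest = max(cluster, key=lambda e: e.summed_intensity)
            n += 1
            out.append(
                NeutralObservation(
                    observation_id=f"obs{n:04d}",
                    M=M,
                    rt=strongest.rt,
                    envelopes=tuple(cluster),
                    SI=si,
                    abundance=abundance_level(si, params),
                    flags=flags,
                )
            )
    return out


def confirm_alkylation(
    native: Sequence[NeutralObservation],
    alkylated: Sequence[NeutralObservation] | None,
    params: MatchParams = MatchParams(),
) -> list[NeutralObservation]:
    """Set the three-disulfide confirmation flag on native observations.

    yes: some alkylated observation sits at M + 348.18 Da within ``alk_tol``;
    no: alkylated data exist but no partner; untested: no alkylated run.
    """
    out: list[NeutralObservation] = []
    for obs in native:
        if alkylated is None:
            out.append(replace(obs, alkylation_confirmed="untested"))
            continue
        hit = any(
            abs(a.M - obs.M - params.alk_delta) <= params.alk_tol for a in alkylated
        )
        out.append(replace(obs, alkylation_confirmed="yes" if hit else "no"))
    return out


def match_predicted(
    candidates: Sequence[MatureCandidate],
    observations: Sequence[NeutralObservation],
    params: MatchParams = MatchParams(),
) -> pd.DataFrame:
    """All (candidate, observation) pairs with |calc - observed| < mass_tol.

    Many-to-many by design; per observation the minimal-|delta| candidate is
    flagged best (ties: lower candidate index).  Columns: observation_id, M,
    rt, SI, abundance, alkylation_confirmed, candidate_id, calc_mass, delta,
    best.
    """
    rows = []
    for obs in observations:
        best_key = None
        best_delta = None
        matches = []
        for k, cand in enumerate(candidates):
            delta = cand.calc_mass - obs.M
            if abs(delta) < params.mass_tol:
                matches.append((k, cand, delta))
                if best_delta is None or abs(delta) < abs(best_delta):
                    best_delta, best_key = delta, k
        for k, cand, delta in matches:
            rows.append(
                {
                    "observation_id": obs.observation_id,
                    "M": obs.M,
                    "rt": obs.rt,
                    "SI": obs.SI,
                    "abundance": obs.abundance,
                    "alkylation_confirmed": obs.alkylation_confirmed,
                    "candidate_id": f"{cand.precursor_id}/cd{cand.cd_index}/off{cand.start_offset:+d}",
                    "precursor_id": cand.precursor_id,
                    "cd_index": cand.cd_index,
                    "start_offset": cand.start_offset,
                    "calc_mass": cand.calc_mass,
                    "delta": delta,
                    "best": k == best_key,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "observation_id", "M", "rt", "SI", "abundance", "alkylation_confirmed",
            "candidate_id", "precursor_id", "cd_index", "start_offset",
            "calc_mass", "delta", "best",
        ],
    )


def abundance_level(SI: float, params: MatchParams = MatchParams()) -> str:
    """low / medium / high on the summed 3+ signal intensity.

    Strictly below si_low is low and strictly above si_high is high; the
    boundary values themselves fall in the closed middle bin.
    """
    if SI < 0:
        raise ValueError("SI must be non-negative")
    if SI < params.si_low:
        return "low"
    if SI > params.si_high:
        return "high"
    return "medium"
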