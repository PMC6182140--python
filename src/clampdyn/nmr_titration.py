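"""Chemical-shift-perturbation titration analysis with shared-Kd fitting.

A receptor observed by ¹H–¹⁵N correlation NMR is titrated with an unlabelled
ligand.  Under fast exchange each backbone amide signal moves from its free
to its bound position in proportion to the bound fraction; the combined
perturbation is

    Δδ = sqrt(ΔδH² + (α·ΔδN)²),        α ≈ 0.2 (¹⁵N down-weighting)

Residues in intermediate exchange instead broaden and disappear at
substoichiometric ligand.  Fitting all fast-exchange residues jointly with a
single dissociation constant against the 1:1 depletion isotherm yields Kd.

Concentrations are in μM throughout; shifts in ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "PRESENT",
    "ABSENT_BROADENED",
    "UNASSIGNED",
    "TitrationPoint",
    "TitrationSeries",
    "CSPResult",
    "KdFit",
    "compute_csp",
    "significance_threshold",
    "classify_residues",
    "binding_isotherm",
    "fit_kd",
    "dilution_track",
    "saturation_check",
    "read_titration_tsv",
    "write_titration_tsv",
]

PRESENT = "present"
ABSENT_BROADENED = "absent_broadened"
UNASSIGNED = "unassigned"


@dataclass
class TitrationPoint:
    """One titration point: concentrations and per-residue amide shifts.

    ``shifts`` maps residue id -> (δH, δN) in ppm; residues lost to
    exchange broadening or never assigned are recorded in ``status``
    instead (values ABSENT_BROADENED / UNASSIGNED).
    """

    ligand_total: float  # μM (0 allowed for the free reference point)
    receptor_total: float  # μM, dilution-corrected
    shifts: dict[object, tuple[float, float]] = field(default_factory=dict)
    status: dict[object, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.receptor_total <= 0:
            raise ValueError("receptor_total must be > 0")
        if self.ligand_total < 0:
            raise ValueError("ligand_total must be >= 0")
        for res, (dh, dn) in self.shifts.items():
            if not (np.isfinite(dh) and np.isfinite(dn)):
                raise ValueError(f"non-finite shift for residue {res!r}")

    @property
    def ratio(self) -> float:
        return self.ligand_total / self.receptor_total


@dataclass
class TitrationSeries:
    """Ordered titration points; point 0 is the ligand-free reference."""

    points: list[TitrationPoint]

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("empty titration series")

    def __len__(self) -> int:
        return len(self.points)

    def residues(self) -> list:
        seen: dict = {}
        for p in self.points:
            for r in p.shifts:
                seen.setdefault(r, None)
            for r in p.status:
                seen.setdefault(r, None)
        return list(seen)


@dataclass
class CSPResult:
    """Per-residue combined shift perturbations between two points."""

    delta: dict  # residue -> Δδ (ppm), NaN if missing
    delta_h: dict
    delta_n: dict
    alpha: float
    missing: dict  # residue -> status flag for residues absent in either point


@dataclass
class KdFit:
    Kd: float  # μM
    ddmax: dict  # residue -> Δδmax (ppm)
    residual_rms: float  # ppm
    converged: bool
    n_residues_used: int
    message: str = ""


def compute_csp(
    point_free: TitrationPoint,
    point_bound: TitrationPoint,
    alpha: float = 0.2,
) -> CSPResult:
    """Combined ¹H/¹⁵N perturbation per residue between two points.

    Δδ = sqrt(ΔδH² + (α·ΔδN)²).  Symmetric in its two arguments.  Residues
    present in only one point carry their missing-status flag and a NaN Δδ.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    common = set(point_free.shifts) & set(point_bound.shifts)
    everyone = set(point_free.shifts) | set(point_bound.shifts) | set(
        point_free.status
    ) | set(point_bound.status)
    if not common:
        raise ValueError("no residues common to the two titration points")
    delta, dh_map, dn_map, missing = {}, {}, {}, {}
    for res in everyone:
        if res in common:
            h0, n0 = point_free.shifts[res]
            h1, n1 = point_bound.shifts[res]
            dh, dn = h1 - h0, n1 - n0
            delta[res] = float(np.hypot(dh, alpha * dn))
            dh_map[res], dn_map[res] = float(dh), float(dn)
        else:
            delta[res] = float("nan")
            flag = point_bound.status.get(res) or point_free.status.get(res) or UNASSIGNED
            missing[res] = flag
    return CSPResult(delta=delta, delta_h=dh_map, delta_n=dn_map, alpha=alpha, missing=missing)


def significance_threshold(csps) -> float:
    """Mean + 2·(population SD) over the finite CSP values.

    The classical cutoff drawn on CSP bar plots: residues above it are
    called significantly perturbed.
    """
    vals = np.asarray(
        [v for v in (csps.values() if isinstance(csps, dict) else csps) if np.isfinite(v)],
        dtype=float,
    )
    if vals.size < 2:
        raise ValueError("need at least 2 finite CSP values")
    return float(vals.mean() + 2.0 * vals.std(ddof=0))


def classify_residues(
    series: TitrationSeries,
    substoich_ratio: float = 1.0,
    noise_ppm: float = 0.005,
    alpha: float = 0.2,
) -> dict:
    """Per-residue exchange-regime class {intermediate, fast, unperturbed}.

    intermediate: the residue becomes absent (broadened) at any point with
    ligand:receptor ratio <= substoich_ratio; fast: present throughout with
    max Δδ above the noise floor; unperturbed: otherwise.  Residues never
    assigned at the reference point are reported as "unassigned".
    """
    if len(series) < 2:
        raise ValueError("need at least 2 titration points")
    ref = series.points[0]
    out: dict = {}
    for res in series.residues():
        if res not in ref.shifts:
            out[res] = UNASSIGNED
            continue
        broadened = any(
            p.status.get(res) == ABSENT_BROADENED and p.ratio <= substoich_ratio
            for p in series.points[1:]
        )
        if broadened:
            out[res] = "intermediate"
            continue
        deltas = []
        for p in series.points[1:]:
            if res in p.shifts:
                csp = compute_csp(ref, p, alpha=alpha)
                deltas.append(csp.delta[res])
        if deltas and max(deltas) > noise_ppm:
            out[res] = "fast"
        else:
            out[res] = "unperturbed"
    return out


def binding_isotherm(receptor_total, ligand_total, Kd):
    """Fraction of receptor bound under the 1:1 depletion isotherm.

    f = ((R + L + Kd) − sqrt((R + L + Kd)² − 4·R·L)) / (2·R)

    Valid for any concentration regime; accounts for ligand depletion,
    unlike the hyperbolic approximation f = L/(L+Kd).
    """
    R = np.asarray(receptor_total, dtype=float)
    L = np.asarray(ligand_total, dtype=float)
    K = np.asarray(Kd, dtype=float)
    if np.any(R <= 0) or np.any(K <= 0) or np.any(L < 0):
        raise ValueError("receptor_total and Kd must be > 0; ligand_total >= 0")
    s = R + L + K
    disc = np.sqrt(np.clip(s * s - 4.0 * R * L, 0.0, None))
    # 2·R·L/(s + disc) is the numerically stable form of (s − disc)/2
    bound = 2.0 * R * L / (s + disc)
    f = bound / R
    return float(f) if np.isscalar(receptor_total) and np.isscalar(ligand_total) else f


def fit_kd(
    series: TitrationSeries,
    fast_residues,
    alpha: float = 0.2,
    xtol: float = 1e-8,
) -> KdFit:
    """Global nonlinear least-squares fit of one shared Kd.

    Observed Δδ(residue, point) is modelled as Δδmax(residue)·f(point; Kd)
    with f the depletion isotherm on the (dilution-corrected) point
    concentrations.  Initial Kd is the first-point receptor concentration;
    initial Δδmax per residue is the last observed Δδ.
    """
    fast_residues = list(fast_residues)
    if len(fast_residues) < 2:
        raise ValueError("need at least 2 fast-exchange residues")
    pts = [p for p in series.points[1:] if p.ligand_total > 0]
    if len(pts) < 4:
        raise ValueError("need at least 4 titration points with ligand")
    ref = series.points[0]

    obs: dict = {res: [] for res in fast_residues}  # res -> [(R, L, dd)]
    for p in pts:
        csp = compute_csp(ref, p, alpha=alpha)
        for res in fast_residues:
            dd = csp.delta.get(res, float("nan"))
            if np.isfinite(dd):
                obs[res].append((p.receptor_total, p.ligand_total, dd))
    obs = {res: rows for res, rows in obs.items() if rows}
    if len(obs) < 2:
        raise ValueError("fewer than 2 fast residues have observable shifts")
    residues = sorted(obs, key=str)
    last_dd = np.array([obs[res][-1][2] for res in residues])
    if np.all(last_dd <= 1e-12):  # ppm; below any real spectrometer precision
        raise ValueError("no signal: all residues have zero maximal CSP")

    def residuals(theta):
        Kd = theta[0]
        r = []
        for k, res in enumerate(residues):
            ddmax = theta[1 + k]
            for R, L, dd in obs[res]:
                r.append(ddmax * binding_isotherm(R, L, Kd) - dd)
        return np.asarray(r)

    x0 = np.concatenate([[series.points[0].receptor_total], np.maximum(last_dd, 1e-6)])
    lb = np.concatenate([[1e-12], np.zeros(len(residues))])
    sol = least_squares(
        residuals, x0, bounds=(lb, np.inf), xtol=xtol, ftol=xtol, gtol=None
    )
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return KdFit(
        Kd=float(sol.x[0]),
        ddmax={res: float(v) for res, v in zip(residues, sol.x[1:])},
        residual_rms=rms,
        converged=bool(sol.success),
        n_residues_used=len(residues),
        message=sol.message,
    )


def dilution_track(
    initial_receptor: float,
    initial_volume: float,
    stock_concentration: float,
    addition_volumes,
) -> pd.DataFrame:
    """Mass-balance concentrations along a stepwise titration.

    After each cumulative addition V_add of ligand stock (concentration
    C_stock) to an initial receptor sample (R₀, V₀):

        receptor_total = R₀·V₀ / (V₀ + V_add)
        ligand_total   = C_stock·V_add / (V₀ + V_add)

    Units are caller-consistent (e.g. μM and μL).  Returns one row per
    point including the zero-addition reference.
    """
    if initial_receptor <= 0 or initial_volume <= 0 or stock_concentration <= 0:
        raise ValueError("initial receptor, volume and stock concentration must be > 0")
    adds = np.asarray(list(addition_volumes), dtype=float)
    if np.any(adds <= 0):
        raise ValueError("addition volumes must be > 0")
    v_cum = initial_volume + np.concatenate([[0.0], np.cumsum(adds)])
    added_cum = v_cum - initial_volume
    receptor = initial_receptor * initial_volume / v_cum
    ligand = stock_concentration * added_cum / v_cum
    return pd.DataFrame(
        {
            "point": np.arange(len(v_cum)),
            "volume": v_cum,
            "receptor_total": receptor,
            "ligand_total": ligand,
            "ratio": np.divide(ligand, receptor),
        }
    )


def saturation_check(
    point_k: TitrationPoint,
    point_k_minus_1: TitrationPoint,
    noise_ppm: float,
    alpha: float = 0.2,
) -> bool:
    """True if the spectrum stopped moving between consecutive additions.

    Saturated iff the largest per-residue Δδ between the two points is
    within (<=) the experimental noise.
    """
    csp = compute_csp(point_k_minus_1, point_k, alpha=alpha)
    vals = [v for v in csp.delta.values() if np.isfinite(v)]
    if not vals:
        raise ValueError("no residues common to the two points")
    # inclusive at the boundary, robust to one-ulp float artifacts
    return max(vals) <= noise_ppm * (1.0 + 1e-9) + 1e-15


# --- TSV interface ---------------------------------------------------------

_TSV_COLUMNS = [
    "residue_id",
    "point_index",
    "ligand_total_uM",
    "receptor_total_uM",
    "dH_ppm",
    "dN_ppm",
    "status",
]


def write_titration_tsv(series: TitrationSeries, path) -> None:
    rows = []
    for k, p in enumerate(series.points):
        for res in sorted(set(p.shifts) | set(p.status), key=str):
            if res in p.shifts:
                dh, dn = p.shifts[res]
                status = PRESENT
            else:
                dh = dn = float("nan")
                status = p.status[res]
            rows.append((res, k, p.ligand_total, p.receptor_total, dh, dn, status))
    df = pd.DataFrame(rows, columns=_TSV_COLUMNS)
    with open(path, "w") as fh:
        fh.write("# clampdyn titration table; concentrations μM, shifts ppm\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_titration_tsv(path) -> TitrationSeries:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"titration TSV missing columns: {sorted(missing)}")
    points = []
    for k in sorted(df["point_index"].unique()):
        sub = df[df["point_index"] == k]
        shifts, status = {}, {}
        for _, row in sub.iterrows():
            if row["status"] == PRESENT:
                shifts[row["residue_id"]] = (float(row["dH_ppm"]), float(row["dN_ppm"]))
            else:
                status[row["residue_id"]] = str(row["status"])
        points.append(
            TitrationPoint(
                ligand_total=float(sub["ligand_total_uM"].iloc[0]),
                receptor_total=float(sub["receptor_total_uM"].iloc[0]),
                shifts=shifts,
                status=status,
            )
        )
    return TitrationSeries(points=points)
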