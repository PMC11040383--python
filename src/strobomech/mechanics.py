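"""Homodyne shear strains and complex dynamic shear modulus maps.

From the complex displacement phasor maps, two in-plane strain combinations
are formed per DIC box (spatial derivatives by central differences on the
box grid, one-sided at borders):

    gamma_p = d(delta_x)/dx + d(delta_y)/dy      ("pure" shear)
    gamma_s = d(delta_x)/dy + d(delta_y)/dx      (simple shear)

Note the first sum is, in standard continuum nomenclature, the planar
divergence rather than the conventional pure shear ``d(delta_x)/dx -
d(delta_y)/dy``; the formula is applied exactly as written here and the
naming kept for continuity with the strain/compliance inversion below.

Dividing the per-direction displacement gradients by the per-direction
stress phasors gives the compliances

    1/G_p = (1/sigma_x) d(delta_x)/dx + (1/sigma_y) d(delta_y)/dy
    1/G_s = (1/sigma_x) d(delta_x)/dy + (1/sigma_y) d(delta_y)/dx

and the reported dynamic modulus is ``G = (G_p + G_s) / 2`` with storage
modulus G' = Re(G) and loss modulus G'' = Im(G).  Because the stress is built
from *velocity* phasors, an elastic in-phase material gives a real G and a
material whose strain lags the stress by pi/2 gives a purely imaginary
(viscous) G — verified against constructed cases in the test-suite.

A direction enters a compliance sum only when its stress amplitude is above a
relative threshold; with one direction excluded, the remaining term alone
defines the compliance (single-component limit G = sigma/gamma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dic import HomodyneDisplacementMap
from .tracking import StressField

__all__ = ["StrainMaps", "ModulusMaps", "shear_strains", "shear_moduli", "modulus_ratio_map"]


@dataclass
class StrainMaps:
    """Complex shear-strain maps and the displacement-gradient components.

    All arrays live on the DIC-box grid; invalid boxes hold NaN.  Gradients
    are dimensionless (um / um).
    """

    gamma_p: np.ndarray
    gamma_s: np.ndarray
    ddx_dx: np.ndarray
    ddx_dy: np.ndarray
    ddy_dx: np.ndarray
    ddy_dy: np.ndarray
    valid: np.ndarray
    spacing_um: float


@dataclass
class ModulusMaps:
    """Complex dynamic shear modulus maps (Pa) on the DIC-box grid.

    ``source`` records how each box was computed: 2 = both G_p and G_s,
    1 = pure only, -1 = simple only, 0 = invalid.
    """

    g_pure: np.ndarray
    g_simple: np.ndarray
    g: np.ndarray
    valid: np.ndarray
    source: np.ndarray

    @property
    def storage(self) -> np.ndarray:
        return self.g.real

    @property
    def loss(self) -> np.ndarray:
        return self.g.imag

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.g)


def _gradient_validity(valid: np.ndarray, axis: int) -> np.ndarray:
    """Boxes whose central/one-sided difference along `axis` uses only valid
    neighbours."""
    v = valid
    prev_ok = np.roll(v, 1, axis=axis)
    next_ok = np.roll(v, -1, axis=axis)
    ok = prev_ok & next_ok  # interior: needs both neighbours
    first = [slice(None)] * v.ndim
    last = [slice(None)] * v.ndim
    first[axis] = 0
    last[axis] = -1
    second = [slice(None)] * v.ndim
    second[axis] = 1
    penult = [slice(None)] * v.ndim
    penult[axis] = -2
    ok[tuple(first)] = v[tuple(second)]
    ok[tuple(last)] = v[tuple(penult)]
    return ok & v


def shear_strains(disp: HomodyneDisplacementMap, spacing_um: float) -> StrainMaps:
    """Strain maps from a homodyne displacement map.

    ``spacing_um`` is the physical DIC-box pitch; displacements are converted
    from fast-camera pixels using the map's pixel pitch (or are taken as
    already physical when none is recorded).  A strain box is valid only when
    every displacement box its stencil touches is valid.
    """
    if disp.delta_x.shape[0] < 2 or disp.delta_x.shape[1] < 2:
        raise ValueError("need at least a 2 x 2 box grid to differentiate")
    scale = disp.pixel_pitch_um if disp.pixel_pitch_um is not None else 1.0
    dx_um = np.where(disp.valid, disp.delta_x, 0.0) * scale
    dy_um = np.where(disp.valid, disp.delta_y, 0.0) * scale
    ddx_dy, ddx_dx = np.gradient(dx_um, spacing_um, spacing_um)
    ddy_dy, ddy_dx = np.gradient(dy_um, spacing_um, spacing_um)
    valid = _gradient_validity(disp.valid, axis=0) & _gradient_validity(disp.valid, axis=1)
    nanc = np.nan * (1 + 1j)
    maps = [np.where(valid, m, nanc) for m in (ddx_dx, ddx_dy, ddy_dx, ddy_dy)]
    return StrainMaps(
        gamma_p=maps[0] + maps[3],
        gamma_s=maps[1] + maps[2],
        ddx_dx=maps[0],
        ddx_dy=maps[1],
        ddy_dx=maps[2],
        ddy_dy=maps[3],
        valid=valid,
        spacing_um=spacing_um,
    )


def shear_moduli(
    strains: StrainMaps,
    stress_x: np.ndarray,
    stress_y: np.ndarray,
    *,
    stress_threshold: float = 0.1,
    min_compliance: float = 1e-12,
) -> ModulusMaps:
    """Complex modulus maps from displacement-gradient and stress phasors.

    ``stress_x`` / ``stress_y`` are the complex stress phasors sampled at the
    DIC-box centres (Pa).  Per box, a direction contributes to the compliance
    sums only if its stress amplitude exceeds ``stress_threshold`` times the
    larger of the two; boxes where both are below threshold, or where a
    compliance magnitude falls under ``min_compliance`` (1/Pa), are invalid.
    """
    sx = np.asarray(stress_x, dtype=complex)
    sy = np.asarray(stress_y, dtype=complex)
    mags = np.stack([np.abs(sx), np.abs(sy)])
    ref = mags.max(axis=0)
    use_x = mags[0] > stress_threshold * ref
    use_y = mags[1] > stress_threshold * ref
    any_dir = (use_x | use_y) & (ref > 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        inv_x = np.where(use_x, 1.0 / np.where(use_x, sx, 1.0), 0.0)
        inv_y = np.where(use_y, 1.0 / np.where(use_y, sy, 1.0), 0.0)
        inv_gp = strains.ddx_dx * inv_x + strains.ddy_dy * inv_y
        inv_gs = strains.ddx_dy * inv_x + strains.ddy_dx * inv_y

    def _invert(inv_g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ok = strains.valid & any_dir & np.isfinite(inv_g) & (np.abs(inv_g) > min_compliance)
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(ok, 1.0 / np.where(ok, inv_g, 1.0), np.nan + 0j)
        return g, ok

    g_pure, ok_p = _invert(inv_gp)
    g_simple, ok_s = _invert(inv_gs)
    both = ok_p & ok_s
    g = np.full(g_pure.shape, np.nan + 0j)
    g[both] = 0.5 * (g_pure[both] + g_simple[both])
    only_p = ok_p & ~ok_s
    only_s = ok_s & ~ok_p
    g[only_p] = g_pure[only_p]
    g[only_s] = g_simple[only_s]
    source = np.zeros(g.shape, dtype=np.int8)
    source[both] = 2
    source[only_p] = 1
    source[only_s] = -1
    return ModulusMaps(
        g_pure=g_pure,
        g_simple=g_simple,
        g=g,
        valid=source != 0,
        source=source,
    )


def modulus_ratio_map(moduli: ModulusMaps) -> np.ndarray:
    """Elementwise log10(G' / G''); boxes with a non-positive component are NaN."""
    gp = moduli.storage
    gl = moduli.loss
    out = np.full(gp.shape, np.nan)
    ok = moduli.valid & (gp > 0) & (gl > 0)
    out[ok] = np.log10(gp[ok] / gl[ok])
    return out
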