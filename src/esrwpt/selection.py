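"""Selection of the decomposition level and the structure-bearing node.

The recipe mirrors how a spectroscopist walks the packet tree: the level-1
detail holds noise, so the D1 subtree is rejected outright and decomposition
follows the approximation chain.  At the optimal level L the pure
approximation node ("A"*L) is a smooth envelope showing only the coarse
hyperfine lines, while the detail split off one level earlier
("A"*(L-2) + "D") — or its approximation child — carries the
(super)hyperfine comb as an evenly spaced oscillation.

Auto mode scans levels 3..N-1 bottom-up and returns the first candidate
node carrying a credible even multiplet.  Credible means three physical
guards all hold — they matter because band-passed noise oscillates
quasi-periodically at any band's characteristic frequency:

* the group's implied ripple frequency 1/spacing lies inside the candidate
  node's nominal frequency band (Gray-code ordering), rejecting leakage
  from adjacent bands;
* the group sits on or beside a coarse line of the envelope — structure
  rides on resonance lines, noise is everywhere;
* the group's amplitude clears a noise floor extrapolated from the D1
  node, which holds only noise by the method's own premise.

Fixed mode applies the level-4 default recipe used for unresolved spectra,
independent of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .peaks import MultipletGroup, detect_peaks, find_even_groups
from .spectra import strip_pads
from .wpt import WPTTree, node_band

__all__ = ["SelectionResult", "select_components", "group_amplitude"]


@dataclass
class SelectionResult:
    level: int
    envelope_path: str
    structure_path: str
    rationale: str  # "auto" | "fixed_default" | "user"
    diagnostics: dict = dc_field(default_factory=dict)


def group_amplitude(
    g: MultipletGroup, field: np.ndarray, component: np.ndarray
) -> float:
    """Median |component| at the group's line positions: how strongly the
    multiplet stands out, in the signal's own units."""
    return float(np.median(np.interp(g.line_positions, field,
                                     np.abs(component))))


def group_quality(
    g: MultipletGroup, field: np.ndarray, component: np.ndarray
) -> float:
    """Evidence that a group is a genuine multiplet rather than chance
    alignment of noise peaks: amplitude times the lines beyond the minimum
    of 3 needed to define evenness at all."""
    return group_amplitude(g, field, component) * (g.n_lines - 2)


def _n_peaks(tree: WPTTree, path: str, prominence: float, peak_mode: str) -> int:
    f, c = strip_pads(tree.source, tree.reconstruct(path))
    return len(detect_peaks(c, f, prominence=prominence, mode=peak_mode))


def comb_supported_by_raw(raw: np.ndarray, freq: float,
                          n_ref: int | None = None) -> bool:
    """Does the raw signal's power spectrum carry a genuine lobe at `freq`
    (cycles/sample)?

    A real comb leaves a local lobe: its neighborhood must stand 3x above
    the surrounding continuum and the local power maximum must sit at the
    comb frequency itself, not merely leak in from a displaced feature or a
    falling continuum.
    """
    n = len(raw)
    n_ref = n_ref or n
    power = np.abs(np.fft.rfft(raw - np.mean(raw))) ** 2
    fgrid = np.fft.rfftfreq(n)
    near = np.abs(fgrid - freq) <= max(0.075 * freq, 1.5 / n_ref)
    surround = (fgrid >= 0.65 * freq) & (fgrid <= 1.5 * freq) & ~near
    if not near.any() or not surround.any():
        return True  # too little spectral support to judge
    base = float(np.median(power[surround]))
    if base > 0 and float(np.mean(power[near])) < 3.0 * base:
        return False
    local = (fgrid >= 0.85 * freq) & (fgrid <= 1.15 * freq)
    if local.any():
        f_loc = float(fgrid[local][np.argmax(power[local])])
        if abs(f_loc - freq) > max(0.10 * freq, 1.5 / n_ref):
            return False
    return True


def _valid_groups(tree, path, envelope_path, noise_sigma, prominence, cv_tol,
                  min_lines, peak_mode, lattice_tol=0.08, band_margin=0.05):
    """(accepted groups, total group count) for one candidate node.

    A group is accepted only when

    * its ripple frequency lies inside the node's nominal band — leakage
      from adjacent bands is periodic too, but at an out-of-band spacing;
    * it sits on or beside a coarse line: within its own span (or 5
      spacings) of a peak of the envelope reconstruction — genuine
      (super)hyperfine structure rides on the coarse lines, while
      band-passed noise oscillates everywhere;
    * its amplitude clears 4x the expected in-band noise floor, estimated
      from the D1 node (pure noise by the method's own premise): white
      noise of per-sample deviation sigma leaves rms sigma * 2**(-d/2) in a
      depth-d node reconstruction;
    * its spacing corresponds to a spectral lobe of the *raw* signal: a
      genuine comb leaves one there, band-passed noise does not.

    Finally the node only counts as structure-bearing when the evidence is
    more than a minimal 3-peak run: either one accepted group has >= 4
    lines, or two accepted groups agree in spacing within 10% (the same
    comb recurring at another coarse line).
    """
    f, c = strip_pads(tree.source, tree.reconstruct(path))
    pl = detect_peaks(c, f, prominence=prominence, mode=peak_mode)
    groups = find_even_groups(pl, cv_tol=cv_tol, min_lines=min_lines,
                              lattice_tol=lattice_tol)
    fe, raw = strip_pads(tree.source)
    fe, ce = strip_pads(tree.source, tree.reconstruct(envelope_path))
    env_peaks = detect_peaks(ce, fe, prominence=prominence, mode=peak_mode)
    # deep envelopes can over-smooth the coarse lines into one bump; the
    # level-3 envelope still resolves them, so use both for proximity
    _, c3 = strip_pads(tree.source, tree.reconstruct("AAA"))
    env3 = detect_peaks(c3, fe, prominence=prominence, mode=peak_mode)
    env_positions = np.concatenate([env_peaks.positions, env3.positions])
    lo, hi = node_band(path)
    width = hi - lo
    step = tree.source.step_gauss
    floor = 4.0 * noise_sigma * 2.0 ** (-len(path) / 2.0)
    # dominant oscillation frequency of the component (cycles/sample):
    # noise can interleave extra peaks and halve a run's apparent spacing,
    # so the accepted spacing must agree with what actually dominates the
    # node's spectrum above the envelope scale
    power = np.abs(np.fft.rfft(c)) ** 2
    fgrid = np.fft.rfftfreq(len(c))
    f_dom = float(fgrid[np.argmax(np.where(fgrid >= lo * 0.5, power, 0.0))])
    # the raw signal's power spectrum: a genuine comb shows a *local* lobe
    # at its frequency there; band-passed noise shows none, and band-edge
    # ringing of strong coarse features merely rides the falling continuum
    raw_power = np.abs(np.fft.rfft(raw - np.mean(raw))) ** 2
    n_raw = len(raw)

    def lobe(freq_c):
        near = np.abs(fgrid - freq_c) <= max(0.075 * freq_c, 1.5 / n_raw)
        surround = (
            (fgrid >= 0.65 * freq_c) & (fgrid <= 1.5 * freq_c) & ~near
        )
        if not near.any() or not surround.any():
            return 0.0, 0.0
        return (
            float(np.mean(raw_power[near])),
            float(np.median(raw_power[surround])),
        )

    accepted = []
    for g in groups:
        freq = step / g.mean_spacing  # cycles per sample
        if not (lo - band_margin * width <= freq <= hi + band_margin * width):
            continue
        if f_dom > 0 and abs(freq - f_dom) > 0.25 * f_dom:
            continue
        near_p, base_p = lobe(freq)
        if base_p > 0 and near_p < 3.0 * base_p:
            continue
        # the local raw-power peak must sit at the group's frequency, not
        # merely leak into its neighborhood from a displaced lobe
        local = (fgrid >= 0.85 * freq) & (fgrid <= 1.15 * freq)
        if local.any():
            f_loc = float(fgrid[local][np.argmax(raw_power[local])])
            if abs(f_loc - freq) > max(0.10 * freq, 1.5 / n_raw):
                continue
        # prefer the fundamental: a genuine, much stronger lobe at half the
        # frequency marks this spacing as a second-harmonic alias
        half_p, half_base = lobe(0.5 * freq)
        if (
            half_base > 0
            and half_p >= 3.0 * half_base
            and near_p > 0
            and half_p > 5.0 * near_p
        ):
            continue
        if len(env_positions):
            dist = float(np.min(np.abs(env_positions - g.center)))
            if dist > max(g.span, 5.0 * g.mean_spacing):
                continue
        if group_amplitude(g, f, c) < floor:
            continue
        accepted.append((g, group_quality(g, f, c)))
    if accepted and not _credible(accepted):
        accepted = []
    return accepted, len(groups)


def _credible(accepted) -> bool:
    """More evidence than one minimal run: a >= 4-line group, or two
    groups concordant in spacing within 10%."""
    if any(g.n_lines >= 4 for g, _ in accepted):
        return True
    spacings = sorted(g.mean_spacing for g, _ in accepted)
    return any(
        b - a <= 0.10 * b for a, b in zip(spacings, spacings[1:])
    )


def _choose_candidate(per_cand: dict[str, float | None]) -> str | None:
    """Pick between the detail node's approximation child and the detail
    itself at one level.

    The child is preferred (one more level of separation from the
    envelope), but only when its comb agrees with the parent's — a child
    whose half-band holds a spacing the parent does not confirm within 10%
    has latched onto distorted edge content, and the parent wins.  True
    agreement between a comb and its half-band image runs at the few-percent
    level, so the gate is 7%.
    """
    paths = list(per_cand)
    child = next((p for p in paths if p.endswith("DA")
                  or (p.endswith("A") and len(p) > 1 and "D" in p)), None)
    parent = next((p for p in paths if p.endswith("D")), None)
    s_child = per_cand.get(child) if child else None
    s_parent = per_cand.get(parent) if parent else None
    if s_child is not None and s_parent is not None:
        if abs(s_child - s_parent) <= 0.07 * s_parent:
            return child
        return parent
    if s_child is not None and s_parent is None and parent is not None:
        # the parent band contains the child's: an unconfirmed child comb
        # is suspect, so require the parent to at least not contradict it
        return child
    if s_parent is not None:
        return parent
    return None


def _candidate_paths(level: int, max_level: int) -> list[str]:
    """Structure candidates at level `level`: the approximation child of the
    detail node when depth allows, plus the detail node itself."""
    parent = "A" * (level - 2) + "D"
    cands = []
    if level <= max_level:
        cands.append(parent + "A")
    cands.append(parent)
    return cands


def select_components(
    t: WPTTree,
    mode: str = "auto",
    fixed_level: int = 4,
    prominence: float = 0.05,
    cv_tol: float = 0.10,
    min_lines: int = 3,
    peak_mode: str = "signed",
    lattice_tol: float | None = 0.08,
) -> SelectionResult:
    """Pick the decomposition level and structure node of a packet tree.

    ``mode="fixed"`` deterministically returns level `fixed_level` with
    envelope ``"A"*L`` and the detail branch ``"A"*(L-2)+"D"`` (preferring
    its approximation child when the tree is deep enough).  ``mode="auto"``
    scans L = 3..N-1, requires the envelope at L to show only the coarse
    lines (same peak count as the level-3 envelope), and keeps the
    strongest in-band even multiplet among the structure candidates; it
    falls back to the fixed recipe (``rationale="fixed_default"``) when no
    level qualifies.  The D1 subtree is never considered.
    """
    if mode not in ("auto", "fixed"):
        raise ValueError(f"unknown mode {mode!r}")
    if fixed_level < 3:
        raise ValueError("fixed_level must be >= 3 (level 2 would select D1)")
    if t.max_level < fixed_level - 1:
        raise ValueError(
            f"tree depth {t.max_level} too shallow for level {fixed_level}"
        )

    if mode == "fixed":
        level = fixed_level
        structure = _candidate_paths(level, t.max_level)[0]
        return SelectionResult(
            level=level,
            envelope_path="A" * min(level, t.max_level),
            structure_path=structure,
            rationale="user",
            diagnostics={"mode": "fixed"},
        )

    # D1 is noise by the method's premise; estimate the white-noise level
    _, d1 = strip_pads(t.source, t.reconstruct("D"))
    noise_sigma = float(np.std(d1)) * np.sqrt(2.0)
    diag: dict = {
        "coarse_lines": _n_peaks(t, "AAA", prominence, peak_mode),
        "noise_sigma": noise_sigma,
        "levels": {},
    }
    top = min(t.max_level, t.p.bit_length() - 2)  # L <= N - 1
    for level in range(3, top + 1):
        env_path = "A" * level
        env_peaks = _n_peaks(t, env_path, prominence, peak_mode)
        level_diag = {"envelope_peaks": env_peaks, "candidates": {}}
        diag["levels"][level] = level_diag
        per_cand = {}
        for cand in _candidate_paths(level, t.max_level):
            accepted, n_groups = _valid_groups(
                t, cand, env_path, noise_sigma, prominence, cv_tol,
                min_lines, peak_mode, lattice_tol,
            )
            spacing = (
                max(accepted, key=lambda tq: tq[1])[0].mean_spacing
                if accepted else None
            )
            per_cand[cand] = spacing
            level_diag["candidates"][cand] = {
                "groups": n_groups,
                "accepted": len(accepted),
                "best_spacing": spacing,
            }
        chosen = _choose_candidate(per_cand)
        if chosen is not None:
            return SelectionResult(
                level=level,
                envelope_path=env_path,
                structure_path=chosen,
                rationale="auto",
                diagnostics=diag,
            )
    # nothing qualified: the unresolved-spectrum default recipe
    level = min(fixed_level, t.max_level)
    diag["fallback"] = True
    return SelectionResult(
        level=level,
        envelope_path="A" * level,
        structure_path=_candidate_paths(level, t.max_level)[0],
        rationale="fixed_default",
        diagnostics=diag,
    )
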