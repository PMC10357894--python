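"""Wavelet packet decomposition of uniform spectra.

A dyadic-length signal of p samples supports N = log2(p) decomposition
levels.  Each level halves every node into an approximation (low band, "A")
and a detail (high band, "D") child, giving the full binary tree of 2**j
nodes at level j.  The filter bank is orthogonal and periodized, so
per-level reconstructions sum exactly to the input and coefficient energy is
conserved (Parseval) to machine precision.

Node paths are written root-to-leaf, e.g. ``"AAD"`` is the detail taken from
the twice-approximated branch.  The spectroscopy literature often writes the
same node with the newest filter first plus the level ("DAA3");
:func:`paper_name` renders that style.

Because the transform is decimated it is not shift covariant: translating
the input by a non-multiple of 2**j permutes energy between nodes at level
j.  Peak *spacings* measured on reconstructions are unaffected, which is
what the downstream analysis relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pywt

from .spectra import UniformSpectrum

__all__ = [
    "WaveletSpec",
    "WPTNode",
    "WPTTree",
    "decompose",
    "reconstruct_node",
    "dwt_chain",
    "paper_name",
    "node_band",
    "max_levels",
]

SUPPORTED_WAVELETS = ("db6", "db9", "coif3")
DEFAULT_WAVELET = "db9"


@dataclass(frozen=True)
class WaveletSpec:
    """An orthogonal wavelet: name plus its four filter banks."""

    name: str
    dec_lo: np.ndarray
    dec_hi: np.ndarray
    rec_lo: np.ndarray
    rec_hi: np.ndarray

    @classmethod
    def from_name(cls, name: str) -> "WaveletSpec":
        if name not in SUPPORTED_WAVELETS:
            raise ValueError(
                f"unsupported wavelet {name!r}; choose from {SUPPORTED_WAVELETS}"
            )
        w = pywt.Wavelet(name)
        return cls(
            name=name,
            dec_lo=np.asarray(w.dec_lo),
            dec_hi=np.asarray(w.dec_hi),
            rec_lo=np.asarray(w.rec_lo),
            rec_hi=np.asarray(w.rec_hi),
        )


def _as_spec(wavelet) -> WaveletSpec:
    if isinstance(wavelet, WaveletSpec):
        return wavelet
    return WaveletSpec.from_name(wavelet)


@dataclass
class WPTNode:
    """One node of the packet tree.

    ``coeffs`` has length p / 2**level; ``recon`` (filled lazily by
    :meth:`WPTTree.reconstruct`) is this node's contribution to the signal at
    full length p, aligned with the field axis.
    """

    path: str
    coeffs: np.ndarray
    recon: np.ndarray | None = None

    @property
    def level(self) -> int:
        return len(self.path)


@dataclass
class WPTTree:
    wavelet: WaveletSpec
    max_level: int
    nodes: dict[str, WPTNode]
    source: UniformSpectrum

    @property
    def p(self) -> int:
        return self.source.field.size

    def node(self, path: str) -> WPTNode:
        if path not in self.nodes:
            valid = sorted(k for k in self.nodes if len(k) == len(path))
            raise KeyError(
                f"no node {path!r}; valid paths at level {len(path)}: {valid}"
            )
        return self.nodes[path]

    def level_paths(self, level: int) -> list[str]:
        return sorted(k for k in self.nodes if len(k) == level)

    def reconstruct(self, path: str) -> np.ndarray:
        """Node-only reconstruction at full length (cached on the node)."""
        node = self.node(path)
        if node.recon is None:
            node.recon = _invert_single_node(
                path, node.coeffs, self.wavelet.name, self.p
            )
        return node.recon


def max_levels(p: int) -> int:
    """N = log2(p) for dyadic p."""
    if p < 2 or p & (p - 1):
        raise ValueError(f"signal length {p} is not a power of two")
    return int(p).bit_length() - 1


def _invert_single_node(path: str, coeffs, wavelet_name: str, p: int):
    if path == "":
        return np.asarray(coeffs, dtype=float).copy()
    wp = pywt.WaveletPacket(
        None, wavelet_name, mode="periodization", maxlevel=len(path)
    )
    wp[path.lower()] = np.asarray(coeffs, dtype=float)
    rec = wp.reconstruct(update=False)
    return np.asarray(rec[:p], dtype=float)


def decompose(u: UniformSpectrum, wavelet=DEFAULT_WAVELET, max_level: int | None = None) -> WPTTree:
    """Full wavelet packet decomposition of `u` down to `max_level`.

    Deterministic; raises a bounds error when `max_level` exceeds
    N = log2(p).
    """
    spec = _as_spec(wavelet)
    p = u.field.size
    n_max = max_levels(p)
    if max_level is None:
        max_level = min(n_max, 8)
    if not 1 <= max_level <= n_max:
        raise ValueError(
            f"max_level {max_level} out of range: signal of length {p} "
            f"admits N = {n_max} levels"
        )
    wp = pywt.WaveletPacket(
        u.intensity, spec.name, mode="periodization", maxlevel=max_level
    )
    nodes: dict[str, WPTNode] = {
        "": WPTNode(path="", coeffs=u.intensity.copy())
    }
    for level in range(1, max_level + 1):
        for nd in wp.get_level(level, "natural"):
            nodes[nd.path.upper()] = WPTNode(
                path=nd.path.upper(), coeffs=np.asarray(nd.data, dtype=float)
            )
    return WPTTree(wavelet=spec, max_level=max_level, nodes=nodes, source=u)


def reconstruct_node(t: WPTTree, path: str) -> np.ndarray:
    """Full-length reconstruction of one node (all other nodes zeroed)."""
    return t.reconstruct(path)


def dwt_chain(u: UniformSpectrum, wavelet=DEFAULT_WAVELET, levels: int = 4):
    """The plain DWT view: [(A1, D1), (A2, D2), ...] as packet-tree nodes."""
    t = decompose(u, wavelet, max_level=levels)
    out = []
    for j in range(1, levels + 1):
        out.append((t.node("A" * j), t.node("A" * (j - 1) + "D")))
    return out


def paper_name(path: str) -> str:
    """Render a root-to-leaf path in newest-filter-first style, e.g.
    ``"AAD"`` -> ``"DAA3"``."""
    if path == "":
        return "root"
    return path[::-1] + str(len(path))


def node_band(path: str) -> tuple[float, float]:
    """Nominal frequency band of a node in cycles/sample (Nyquist = 0.5).

    Packet nodes in natural (filter) order are not frequency ordered; the
    band index follows the binary-reflected Gray code of the path, with
    A = 0 and D = 1.
    """
    if path == "":
        return (0.0, 0.5)
    idx = 0
    prev = 0
    for ch in path:
        bit = {"A": 0, "D": 1}[ch]
        prev = bit ^ prev
        idx = (idx << 1) | prev
    width = 0.5 / 2 ** len(path)
    return (idx * width, (idx + 1) * width)
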