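"""Extract Cu(II) quartet parameters from a g-perp window.

The nitrogen superhyperfine comb is read from the level-3 detail component;
its clean edge groups locate the outer copper lines h-1 and h-4, from which
A(Cu) and the g value follow by exact arithmetic.
"""

from esrwpt import ExtractionConfig, extract, make_benchmark

(spectrum, truth), = make_benchmark("cuqu_like", seed=0)

config = ExtractionConfig(
    region="g_perp",
    windows=[(3050.0, 3460.0)],
    spin_I=1.0,
    mw_frequency_ghz=9.316,
    crop_to_window=True,
)
result = extract(spectrum, config)

print(f"A(N)  = {result.A_fine:.1f} G   (truth {truth['A_fine']} G)")
print(f"n(N)  = {result.n_nuclei}       (truth {truth['n_nuclei']})")
print(f"A(Cu) = {result.A_cu:.1f} G   (truth {truth['A_cu']} G)")
print(f"g     = {result.g_value:.4f}  (truth {truth['g_perp']})")
print("quartet lines h1..h4:",
      [f"{b:.1f}" for b in result.quartet_positions])
# A(Cu) = (h4 - h1)/3 and g = 714.4773 * nu / ((h1 + h4)/2): everything
# follows from the positions of the outer quartet lines.
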