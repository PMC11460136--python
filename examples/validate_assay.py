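"""Run the LOD/LOQ validation study on a simulated dilution series.

Simulates 20-replicate measurements at 1-8% adulteration, then applies the
decision rules: LOD is the lowest level detected in >= 95% of replicates
(stably, i.e. every higher level passes too), LOQ the lowest level with
replicate RSD <= 25%.
"""

from herbq import discover_panel, fritillaria_demo, validate_assay
from herbq.simulate import MixtureSpec, simulate_dilution_series

grouping, alignments = fritillaria_demo(seed=0)
panel = discover_panel(alignments, grouping)

base = MixtureSpec({"F. cirrhosa": 0.2}, seed=3)  # default noise model
table = simulate_dilution_series(
    base, "F. hupehensis", [0.01, 0.02, 0.04, 0.06, 0.08], 20, panel=panel
)

# the adulterant carries the group site's background allele (C)
site = panel.primary
rows = table[
    (table["locus"] == site.locus)
    & (table["position"] == site.position)
    & (table["allele"] == site.background_allele)
][["level", "replicate", "frequency"]]

report = validate_assay(rows)
print("level   n   mean_freq   RSD%    detection")
for s in report.per_level:
    print(f"{s.level:>5.0%}  {s.n:>2}   {s.mean:.4f}     "
          f"{s.rsd:>6.1f}  {s.detection_rate:>8.0%}")
print(f"\nLOD = {report.lod:.0%}, LOQ = {report.loq:.0%}")
print(f"linearity R^2 = {report.linearity.r_squared:.4f}")

# At 1% the relative scatter blows up (RSD far above 25%) and detection is
# unstable; 4% and above pass comfortably.  The 2% level's true RSD sits just
# under the 25% bound, so a single 20-replicate study may return an LOQ of
# 2% or 4% depending on the draw — averaged over many studies the modal
# answer is 2%, the assay's working floor.
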