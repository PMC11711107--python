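"""Map mineral phases in a synthetic SEM-EDS scene and quantify area fractions.

Builds a three-phase scene (quartz, calcite, feldspar) with realistic
per-element intensities and noise, runs the flatten/threshold/assemble
pipeline, and compares recovered area fractions against ground truth.
"""

from geoparticle import fixtures as fx
from geoparticle import phasemap as pm

scene = fx.SceneSpec(
    shape=(96, 96),
    regions=[
        fx.PhaseRegion("quartz", {"Si": 180.0}, ("rect", 6, 6, 54, 54)),
        fx.PhaseRegion("calcite", {"Ca": 160.0}, ("disk", 72, 72, 16)),
        fx.PhaseRegion("feldspar", {"Al": 150.0, "Si": 150.0}, ("rect", 62, 6, 90, 34)),
    ],
    background=10.0,
    noise_sd=14.0,  # 10% of the weakest signal-to-background gap
    seed=42,
)
stack, truth = fx.make_element_stack(scene)

recipe = [
    pm.PhaseDefinition("quartz", {"Si"}, threshold=165, denoise_radius=1, color=(230, 60, 60)),
    pm.PhaseDefinition("calcite", {"Ca"}, threshold=85, denoise_radius=1, color=(60, 130, 230)),
    pm.PhaseDefinition("feldspar", {"Al", "Si"}, threshold=120, denoise_radius=1, color=(70, 190, 90)),
]
phase_map = pm.map_phases(stack, recipe)
table = pm.measure_area_fractions(phase_map)
truth_table = pm.measure_area_fractions(truth)

print("phase        recovered %   truth %")
for phase, pct in table.rows.items():
    print(f"{phase:<12} {pct:>10.2f} {truth_table.rows[phase]:>9.2f}")
print(f"{'unassigned':<12} {table.unassigned_pct:>10.2f}")
# Recovered fractions land within ~1% absolute of truth at this noise level;
# the rows plus 'unassigned' always total 100% of the frame area.
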