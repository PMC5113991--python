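# paracell

Analysis toolkit for paracellular ion transport across epithelial monolayers.
It converts raw transepithelial electrical measurements — resistance (TER) and
dilution potentials recorded with a volt-ohm meter under a NaCl gradient —
into the apparent paracellular permeabilities of Na⁺ and Cl⁻, encodes the
osmotic-gradient bath protocols used to perturb tight-junction selectivity in
MDCK II-like monolayers, and quantifies the tortuosity of cell–cell contacts
(the *zigzag index*). A synthetic-data module generates complete measurement
runs and junction meshes with known ground truth, so every step of the
pipeline can be validated end to end without wet-lab data.

Intended users: epithelial physiologists and tight-junction biologists
analyzing Transwell dilution-potential experiments, and anyone needing a
tested reference implementation of the constant-field selectivity math.

## The model

For a barrier permeable to Na⁺ and Cl⁻ with selectivity ratio
β = P_Na/P_Cl, the zero-current **Goldman–Hodgkin–Katz dilution potential**
(apical minus basal) is

```
V = (RT/F) · ln[ (β·[Na]_b + [Cl]_a) / (β·[Na]_a + [Cl]_b) ]
```

so a measured potential under a known NaCl gradient inverts in closed form to
β. The **Kimizuka–Koketsu decomposition** then splits the blank-corrected
conductance G = 1/TER into absolute permeabilities:

```
G = (F²/RT) · (P_Na·C̄_Na + P_Cl·C̄_Cl),   P_Cl = P_Na/β
```

with C̄ the per-ion logarithmic mean of the apical and basal concentrations
(arithmetic-mean and basal-only variants are selectable). Blank-filter
resistance and potential are subtracted time point by time point before
inversion. The zigzag index is L_TJ/L_St: the ratio of the summed traced
contour lengths of all contact sides in five randomly placed 815-µm² windows
to the summed straight end-to-end lengths of the same sides.

## Worked example

```python
import numpy as np
from paracell import (NoiseModel, blank_correct, compute_permeability_series,
                      preset_library, recovery_metrics, simulate_run)

model = preset_library()["wt_reversibility"]   # apical hyposmolality, reversed at 120 min
noise = NoiseModel(sigma_v=0.0, sigma_r=0.0, seed=0)
sample, blank, truth = simulate_run(model, noise, grid=np.array([5.0, 120.0, 125.0]))
df = compute_permeability_series(blank_correct(sample, blank),
                                 model.condition.schedule())
print(df[["time_min", "beta", "p_na_cm_s"]].to_string(index=False))
print("recovery triple:", recovery_metrics(df))
```

prints

```
 time_min   beta  p_na_cm_s
      5.0  22.41   0.000046
    120.0   3.40   0.000033
    125.0  16.55   0.000027
recovery triple: (22.41000000000006, 3.3999999999999977, 16.54999999999997)
```

i.e. the monolayer's cation selectivity P_Na/P_Cl collapses from 22.4 to 3.4
over two hours of apical hyposmolality and rebounds to 16.6 within five
minutes of removing the osmotic gradient, while the absolute Na⁺ permeability
(46 → 33 → 27 ×10⁻⁶ cm/s) does not fully recover — the signature of a
reversible, selectivity-specific tight-junction response.

The same flow is available from the shell:

```
paracell simulate --preset wt_hypo --seed 1 --replicates 4 --out-dir run/
paracell analyze  --measurements run/measurements.csv \
                  --condition apical_hyposmotic --out run/permeability.csv
paracell mesh     --seed 2 --jag-amplitude 1.5 --jag-period 3 --out mesh.csv
paracell zigzag   --graph mesh.csv --seed 3 --out zigzag.csv
paracell report   --inputs run/permeability.csv --out summary.csv
```

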