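# lungvar

Quantitative assessment of respiratory motion-mitigation quality from
repeated breath-hold MRI, for medical-physics and radiotherapy research.

Motion-mitigated irradiation of lung tumours — in particular pencil-beam
scanning proton therapy — requires lung structures to sit in reproducible
positions scan after scan, visit after visit.  `lungvar` implements the
analysis chain used to compare two mitigation methods, an enhanced
deep-inspiration breath hold (eDIBH) and high-frequency percussive
ventilation (HFPV), on a design of 21 subjects × 4 weekly visits × 2
consecutive scans per method:

* **Lung-volume segmentation** — per-plane adaptive (Otsu) thresholding of a
  3D voxel grid, 2D labelling with border/area filtering, 3D 26-connected
  clustering, and voxel-count volumetry.
* **Lung-structure metric** — for each scan, the difference vectors
  **r**ᵢ between nine mobile lung structures (apex, carina, diaphragm, six
  vessel branch points) and a motion-invariant spinal reference Ref_SC; over
  a method's 8 scans the radial distances rᵢ = |**r**ᵢ| give per-structure
  means μ(rᵢ, M), SDs σ(rᵢ, M) and fractional variations σ/μ.
* **Method comparison** — the log-ratio
  γ = log₁₀[(σ/μ)_eDIBH / (σ/μ)_HFPV] per subject and structure (negative ⇔
  less variability with eDIBH), per-structure Wilcoxon signed-rank tests on
  paired relative errors, per-subject preference counts, and a binomial
  preference model.
* **Setup correction & variability ellipsoids** — rigid transforms estimated
  from spine landmarks (Kabsch least squares), translation-only correction
  (simulating couch offset correction), per-axis SD decomposition of the
  corrected position clusters, and the 95 %-CL "volume of variability"
  VolOfVar = (4/3)π k³ σ_RL σ_AP σ_CC with k = √χ²₀.₉₅(3 df) ≈ 2.7955,
  normalised by mean lung volume and compared between methods as a log₁₀
  ratio.
* **Synthetic cohort generator** — seeded landmark tables, per-scan lung
  volumes, setup transforms and analytic thorax phantoms with exactly known
  lung volume, so the entire pipeline is testable without imaging data.

## Worked example

```python
from lungvar import CohortConfig, generate_cohort
from lungvar.metrics import (radial_distance_table, variation_table,
                             gamma_table, volume_variation_table,
                             count_preferences)

cohort = generate_cohort(CohortConfig(seed=42))
variation = variation_table(radial_distance_table(cohort.landmarks))
gamma = gamma_table(variation, volume_variation_table(cohort.landmarks))
prefs = count_preferences(gamma)
print(f"{prefs.n_negative}/{prefs.n_defined} negative, "
      f"{100*prefs.overall_negative_fraction:.0f}% favour eDIBH")
```

prints

```
175/210 negative, 83% favour eDIBH
```

i.e. of the 210 γ log-ratios (21 subjects × 10 entries: 9 structures plus
lung volume), 175 are negative — under the generator's default noise model
(diaphragm and lower-vessel noise 2–3× larger for HFPV, differences mostly
in AP/CC) most subject-structure pairs are more reproducible under eDIBH.
The `examples/` directory contains one narrative script per capability
(cohort generation, phantom segmentation, method comparison, variability
ellipsoids); each prints the numbers it computes and what they mean.

A thin CLI mirrors the pipeline stages:

```bash
lungvar generate --seed 1 --out landmarks.csv
lungvar segment --in phantom.nii --report report.json
lungvar run-study --seed 1 --out bundle/
```

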