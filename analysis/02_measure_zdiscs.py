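"""Segment the simulated fields and compare Z-disc sizes between genotypes.

Auto-thresholds each field, extracts particles (≥0.2 µm², borders
excluded), measures disc diameters as bounding-box height, bins them into
size categories, and tests control vs mutant with Fisher's exact test.
Relative fluorescence intensities (normalized to the control mean) are
compared with Welch's t-test.

Requires: analysis/01_simulate_dataset.py has been run.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from zdiscquant.image import read_calibrated_tiff
from zdiscquant.segmentation import (
    auto_threshold_default_dark,
    categorize_sizes,
    find_particles,
    mean_intensity_per_particle,
    measure_diameter,
)
from zdiscquant.stats import ContingencyTable, fisher_exact, normalize_to_control, welch_t_test

IMAGES = Path("scratch/simulated")
OUT = Path("results")


def main() -> None:
    fields = pd.read_csv(OUT / "simulated_fields.csv")
    fields = fields[fields.dataset == "size"]
    rows, diameters, intensities = [], {}, {}
    for _, f in fields.iterrows():
        img = read_calibrated_tiff(IMAGES / f.field)[0]
        particles = find_particles(auto_threshold_default_dark(img), img)
        means = mean_intensity_per_particle(img, particles)
        diameters.setdefault(f.group, [])
        intensities.setdefault(f.group, [])
        for p, mi in zip(particles, means):
            d = measure_diameter(p)
            diameters[f.group].append(d)
            intensities[f.group].append(mi)
            rows.append({"group": f.group, "field": f.field, "area_um2": p.area_um2,
                         "diameter_um": d, "mean_intensity": mi})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "zdisc_particles.csv", index=False)

    table = categorize_sizes(diameters)
    cat = pd.DataFrame(
        {g: c for g, c in table.counts.items()}, index=table.bin_labels()
    ).rename_axis("size_category_um")
    cat.to_csv(OUT / "zdisc_size_categories.csv")

    mat = np.stack([table.counts["control"], table.counts["mutant"]])
    mat = mat[:, mat.sum(axis=0) > 0]
    fisher = fisher_exact(ContingencyTable(mat))
    rel_c = normalize_to_control(intensities["control"], intensities["control"])
    rel_m = normalize_to_control(intensities["mutant"], intensities["control"])
    welch = welch_t_test(rel_c, rel_m)
    pd.DataFrame(
        [
            {"comparison": "size_categories", "method": fisher.method, "p_value": fisher.p_value},
            {"comparison": "relative_intensity", "method": welch.method,
             "statistic": welch.statistic, "df": welch.df, "p_value": welch.p_value},
        ]
    ).to_csv(OUT / "zdisc_stats.csv", index=False)

    print(cat.to_string())
    for g in ("control", "mutant"):
        print(f"{g}: n={len(diameters[g])} discs, median diameter "
              f"{np.median(diameters[g]):.2f} µm")
    print(f"\nFisher exact on size categories: p = {fisher.p_value:.3g} "
          f"({'significant' if fisher.p_value <= 0.001 else 'not significant'} at the "
          f"0.001 convention)")
    print(f"Welch on relative intensity: t = {welch.statistic:.2f}, p = {welch.p_value:.3g}")
    n_small = sum(1 for d in diameters["mutant"] if d < 0.9)
    if n_small == 0:
        print(
            "Note: the smallest mutant discs (0.70 µm true diameter) fall below the "
            "0.2 µm² particle-area filter and are never measured — the procedure's "
            "size-exclusion bias, which also depresses the mutant group's apparent "
            "mean intensity (the PSF dilutes small objects)."
        )


if __name__ == "__main__":
    main()
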