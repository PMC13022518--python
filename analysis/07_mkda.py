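#!/usr/bin/env python
"""Coordinate-based meta-analysis with bootstrap category balancing.

Generates a synthetic 16 vs 9 study corpus with a striatal-like planted
cluster in the mixed-context category, runs the bootstrap-balanced
mixed > only MKDA contrast with permutation FWE thresholds, and quantifies
the overlap of the final map with the planted ground-truth region.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from contextrl.mkda import bootstrap_contrast, density_map, \
    make_synthetic_mask, overlap_fraction, save_map
from contextrl.synth import SyntheticFociSpec, simulate_foci


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--radius", type=float, default=10.0, help="kernel mm")
    ap.add_argument("--n-boot", type=int, default=50,
                    help="bootstrap iterations (500 for the full run)")
    ap.add_argument("--subset-size", type=int, default=9)
    ap.add_argument("--consistency", type=float, default=0.05)
    ap.add_argument("--n-perm", type=int, default=199,
                    help="permutations per threshold (1000 for the full run)")
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--grid", type=int, default=32, help="grid side (voxels)")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    mask, grid = make_synthetic_mask((args.grid,) * 3, 2.0)
    spec = SyntheticFociSpec()
    studies = simulate_foci(spec, grid, mask, seed=args.seed)
    mixed = [s for s in studies if s.category == "reward_mixed"]
    only = [s for s in studies if s.category == "reward_only"]
    n_foci = sum(len(s.foci) for s in studies)
    n_part = sum(s.n_participants for s in studies)
    print(f"corpus: {len(mixed)} mixed + {len(only)} reward-only studies, "
          f"{n_foci} coordinate sets, {n_part} participants")

    final, freq = bootstrap_contrast(
        mixed, only, grid, mask, args.radius, n_boot=args.n_boot,
        subset_size=args.subset_size, consistency=args.consistency,
        n_perm=args.n_perm, alpha=args.alpha, seed=args.seed)

    # ground-truth cluster region: kernel-sized ball around the planted center
    truth = np.zeros(grid.shape, dtype=bool)
    center = grid.mm_to_vox(spec.cluster_center)[0]
    ijk = np.indices(grid.shape).reshape(3, -1).T
    d2 = ((ijk - center) ** 2).sum(axis=1) * grid.voxel_size**2
    truth.ravel()[d2 <= args.radius**2] = True
    truth &= mask

    overlap = overlap_fraction(final, truth, mask)
    center_hit = bool(final[tuple(center)])
    print(f"final contrast map: {int(final.sum())} voxels "
          f"(consistency >= {args.consistency:.0%} of {args.n_boot} iterations)")
    print(f"planted center voxel recovered: {center_hit}; "
          f"{overlap:.1f}% of final-map voxels lie in the planted region")

    args.out_dir.mkdir(parents=True, exist_ok=True)
    save_map(freq, grid, args.out_dir / "mkda_frequency.nii.gz")
    save_map(final.astype(float), grid, args.out_dir / "mkda_contrast.nii.gz")
    (args.out_dir / "mkda.json").write_text(json.dumps({
        "n_mixed": len(mixed), "n_only": len(only),
        "n_coordinate_sets": int(n_foci), "n_participants": int(n_part),
        "final_map_voxels": int(final.sum()),
        "center_recovered": center_hit,
        "overlap_with_planted_percent": overlap}, indent=2))


if __name__ == "__main__":
    main()
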