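# emval

Validation of atomic models against cryo-EM density maps: global and
per-residue fit-to-map scores, false-discovery-rate confidence maps,
stereochemical validation, difference maps and model-based local
sharpening, plus a collation step that flags low-scoring residues and
clusters them by spatial proximity so the worst structural neighbourhoods
surface first.

## What it computes

* **Fit to data** — Fourier shell correlation between the experimental map
  and a map simulated from the model; the count-weighted **FSCavg** up to a
  user-stated resolution; masked real-space correlation; per-residue
  sliding-window Manders' overlap (**SMOC**).
* **Confidence maps** — one-sided Gaussian background test per voxel with
  Benjamini–Yekutieli FDR control (Benjamini–Hochberg switchable), and the
  per-residue **FDR-backbone** score (fraction of backbone atoms in
  confidently-signal voxels), which localises backbone mis-tracing.
* **Geometry** — riding-hydrogen placement, clashscore (vdW overlap >= 0.4 A,
  H-bond pairs excluded), Ramachandran classification and Z-score, rotamer
  outliers, CA-trace virtual-dihedral outliers, and the logarithmic
  composite geometry score (0.5 = perfect).
* **Amplitude tools** — Wilson (log-amplitude vs s^2) curves with an
  over-sharpening detector, global shell-wise amplitude scaling, two-way
  difference maps, and rolling-window local amplitude scaling against a
  model-derived reference.
* **Collation** — per-metric thresholds flag residues, flagged residues are
  single-linkage clustered on CA–CA distance (default 8 A) and ranked by
  severity; contact listing at any residue site; before/after comparison
  (dFSC, dMolProbity-style delta).
* **Synthetic fixtures** — ideal poly-Ala helices, simulated noisy maps and
  seeded defects (segment shift, register shift, rotamer scramble, clash
  injection, deletions) so the whole pipeline is testable offline.

Formats: MRC2014/CCP4 maps (modes 0/1/2, axis order normalised, ORIGIN
taking precedence over NSTART), PDB and mmCIF models.

## Command line

Every subcommand echoes its parameters into the report; the nominal
resolution is always user-supplied, never inferred from the map.

```sh
# synthetic inputs to play with
emval fixtures --n-res 30 --resolution 3 --noise 0.3 --seed 1 --out fix

# full validation report (JSON + CSV + text summary into a directory)
emval validate --map fix.mrc --model fix.pdb --resolution 3.0 --out report/

# individual tasks
emval fit        --map fix.mrc --model fix.pdb --resolution 3.0 --out run1
emval geometry   --model fix.pdb --out run1
emval confidence --map fix.mrc --model fix.pdb --fdr 0.01 --out run1
emval diffmap    --map fix.mrc --model fix.pdb --resolution 3.0 --out run1
emval locscale   --map fix.mrc --model fix.pdb --resolution 3.0 --window 12 --out sharp.mrc
emval contacts   --model fix.pdb --chain A --resnum 10
emval compare    --before report_a/report.json --after report_b/report.json
```

Exit codes: 0 success, 2 input/usage error, 1 internal error.  A
`--config file` of `key=value` lines can supply defaults; command-line
values win.

## Notes on reference data

The Ramachandran, rotamer and CA-trace probability surfaces shipped in
`emval.geometry_validation.refdata` are coarse smoothed mixtures centred on
canonical conformations; classification uses contour levels (favored >= the
98% mass contour, outlier < the 99.95% contour), so basin shape matters
rather than absolute calibration.  Absolute outlier percentages can differ
from probe-based validators by small margins; all thresholds are declared
constants in that module.
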