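# rigidall

Rigidity-based allostery analysis of protein structures: conformational
comparison of open/closed states, FIRST-style molecular constraint
networks, (6,6) body-bar pebble-game rigid-cluster decomposition,
rigidity-transmission allostery (RTA) scans with AUC summaries, elastic
network models (GNM/ANM), backbone transition-zone peptide-geometry
statistics, and in silico point-mutation rigidity diffs.

Every stage is testable without downloads through the `rigidall.synthetic`
generators, which produce body-bar frameworks of known degrees of freedom,
ideal helices with applied rotations, two-site networks with a planted
DOF-transmission count, and backbone ensembles with planted phi
trajectories and peptide-geometry distortions.

## Modules

| module | contents |
| --- | --- |
| `rigidall.structure` | PDB/mmCIF reading & writing, ensembles, polar-hydrogen placement, ligand-neighborhood selection |
| `rigidall.compare` | Kabsch superposition, per-residue CA RMSD, residue-pair distances, backbone dihedrals, helix rotation angles, buried interface areas (Shrake–Rupley), residue interaction networks + diffs |
| `rigidall.network` | covalent bond detection, Mayo-potential hydrogen bonds, hydrophobic tethers, constraint networks, H-bond dilution series |
| `rigidall.rigidity` | (6,6) body-bar pebble game, DOF counting, rigid-cluster decomposition (`rigidall._pebble` holds the numba-accelerated kernel) |
| `rigidall.rta` | DOF transmission between sites, 3-residue sliding-window scans, transmission intensity profiles, AUC, hotspot calls |
| `rigidall.enm` | GNM/ANM modes, frequency dispersion, collectivity, domain splits & hinges, mode overlap |
| `rigidall.transition` | per-frame backbone dihedrals/angles/O(-1)···C distances, transition-zone scans, quadratic & cosine distortion fits, Ramachandran densities |
| `rigidall.mutation` | idealized side-chain rebuilding with a coarse rotamer search, wild-type vs mutant rigidity diffs |
| `rigidall.synthetic` | ground-truth fixture generators |
| `rigidall.pipeline` / `rigidall.cli` | end-to-end orchestration and the `rigidall` command |
| `rigidall.targets` | the headline glutamate-dehydrogenase reproduction measurements |

## CLI

```bash
rigidall run --outdir demo_out          # demo pipeline on synthetic fixtures
rigidall compare ref.pdb mobile.pdb     # CA superposition + RMSD profile
rigidall network structure.pdb --cutoff -0.5
rigidall rigidity structure.pdb         # rigid-cluster decomposition
rigidall rta structure.pdb --ligand GTP # transmission scan toward a site
rigidall enm structure.pdb --kind gnm --mode 2
rigidall geometry ensemble.pdb          # peptide-geometry records
rigidall mutate structure.pdb SER441LEU
```

For the full reproduction, write a config JSON (see
`rigidall.pipeline.PipelineConfig`) with
`inputs = {"apo": ..., "open": ..., "closed": ...}` and run
`rigidall run --config config.json`.

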