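# File formats

## Volumes — NIfTI-1 (`.nii`, `.nii.gz`)

Read and written through nibabel.  Conventions:

* The anterior–posterior (slice-stacking) axis is the **third voxel
  axis**.  Reconstructions passed to `slabimpute impute` are ordered
  stacks `(H, W, n_slices)`; RGB volumes carry the channel as a fourth
  dimension `(H, W, n_slices, 3)`.
* Integer datatypes (label maps) round-trip exactly; affines to 1e-6.
* Per-slice AP world coordinates come from the affine's AP spacing for
  uniform stacks, or from a `--coords` text file (one mm value per
  line, strictly increasing) for non-uniform slabbing.

## Meshes — ASCII OFF (`.off`)

Standard Object File Format, triangles only:

    OFF
    <n_vertices> <n_faces> 0
    x y z            # one vertex per line, world mm
    ...
    3 i j k          # one triangular face per line, 0-based indices
    ...

Per-vertex parcel labels live in a sidecar text file (default
`<mesh>.labels.txt`), one integer per line, aligned with the vertex
order.

## Configurations — YAML

`RunConfig` bundles the generator ranges (`synth`), optimization
hyperparameters (`train`), architecture (`unet`) and a seed; it
round-trips losslessly through YAML and hashes stably for provenance
logging.

## Checkpoints — `.npz`

A single NumPy archive: every parameter array under `param//<name>`,
plus a JSON metadata record (format version, architecture, training
config hash).  Loading rebuilds the network and reproduces forward
outputs bit-exactly.

## Metric tables — TSV

`slabimpute evaluate ...` writes tab-separated tables (pandas), one row
per region/vertex/parcel.
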