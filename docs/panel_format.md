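# Reference panel file format (`.rcsf`)

A panel is a single JSON document (UTF-8, no compression) so panels are
diffable, portable and inspectable with standard tools. Floats are written
with Python's shortest-exact-decimal `repr`, so save → load round-trips
bit-identically.

Top-level keys (`schema_version` = 1):

| key | type | meaning |
|---|---|---|
| `schema_version` | int | format version; loaders reject unknown versions |
| `panel_kind` | `"csf"` or `"plasma"` | which fluid the panel was built from; the pipeline is otherwise identical |
| `n_samples` | int | number of euploid samples used |
| `k_components` | int | PCA components removed during normalization |
| `grid` | object | `width` plus the full chromosome table (`name`, `length`, `centromere_start`, `centromere_end`, `acrocentric`), sufficient to rebuild the interval grid exactly |
| `mu` | float array, grid length | per-interval mean read proportion (zero on unscored intervals) |
| `sigma` | float array, grid length | moderated, floored per-interval residual SD |
| `components` | k × n_scored float matrix | orthonormal PCA loadings over the scored intervals, row-major |
| `gene_mu` | object | gene name → expected read fraction of its registered focal window |

The grid is re-derived from the embedded layout on load, so a panel file is
self-contained: no separate layout file is needed to score samples against
it.
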