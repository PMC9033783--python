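# Annotation file format (version 1.0)

One JSON file per reader per study. Geometry is stored as WKT so the
format is language-neutral, diffable and round-trips to at least 1e−9
coordinate precision.

```json
{
  "format_version": "1.0",
  "reader_id": "reader_a",
  "coordinate_convention": "pixel, x=col, y=row, centers at integers",
  "entries": {
    "<SOP Instance UID>": {
      "lv_endo":      "POLYGON ((...))",
      "lv_myo":       "POLYGON ((outer ring), (inner ring))",
      "rv_endo":      "POLYGON ((...))",
      "lv_papillary": "MULTIPOLYGON (((...)), ((...)))"
    }
  }
}
```

Rules:

- Keys of `entries` are DICOM SOP Instance UIDs; every annotated UID must
  exist in the image set of the case being built.
- Coordinates are continuous pixel coordinates of the referenced image:
  `x` along columns, `y` along rows, pixel centers at integer positions
  (pixel `(r, c)` covers `[c−0.5, c+0.5] × [r−0.5, r+0.5]`). Physical
  spacing is taken from the DICOM tags at metric time, never stored here.
- Contour names come from the vocabulary `lv_endo`, `lv_myo`, `rv_endo`,
  `lv_papillary`. Vendor names can be mapped via the config's
  `contour_aliases`; unknown names are rejected unless
  `allow_unknown_contours` is set.
- `lv_myo` is an annulus: exterior ring = epicardial border, one interior
  ring = endocardial border. `lv_papillary` and `rv_endo` may be
  multipolygons. `POLYGON EMPTY` is a valid entry (image seen, structure
  absent).
- Unknown `format_version` values are rejected explicitly.
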