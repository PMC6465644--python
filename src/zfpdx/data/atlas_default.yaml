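# Default anatomical region atlas for 48-72 hpf zebrafish embryos.
#
# Coordinate convention: origin (0, 0) at the injection site in the
# pericardial space (PCS); x is the anteroposterior axis in micrometres,
# positive toward the tail; y is the dorsoventral axis, positive toward
# dorsal.  Each region is an axis-aligned rectangle [x0, x1) x [y0, y1);
# together the rectangles tile the embryo bounding box.  The geometry is a
# schematic stand-in ordered by hemodynamics (brain channels and mandibular
# arch anterior, yolk and trunk vessels medial, cardinal vein / caudal
# hematopoietic tissue / caudal fin posterior); edit freely for a different
# mounting or stage.
regions:
  PMBC:  {x0: -1200, x1: -600, y0:    0, y1: 400}
  PHBC:  {x0: -1200, x1: -600, y0: -400, y1:   0}
  AA1:   {x0:  -600, x1: -100, y0: -400, y1: 400}
  PCS:   {x0:  -100, x1:  300, y0: -400, y1: 400}
  Yolk:  {x0:   300, x1: 1800, y0: -400, y1:   0}
  ISV:   {x0:   300, x1: 1800, y0:    0, y1: 250}
  DLAV:  {x0:   300, x1: 1800, y0:  250, y1: 400}
  PCV:   {x0:  1800, x1: 2600, y0: -400, y1: 400}
  CHT:   {x0:  2600, x1: 3200, y0: -400, y1: 400}
  CF:    {x0:  3200, x1: 3600, y0: -400, y1: 400}
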