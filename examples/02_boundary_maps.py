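"""Build the two kinds of boundary supervision maps from one mask.

The sampled-points map stamps each key point as a small disk; the
boundary-mask map marks the full one-pixel inner boundary.  Both are the
[0,1] targets the network's deep-supervision heads are trained against.
"""

import boundaryseg as bs

spec = bs.PhantomSpec(seed=7)
mask = bs.sample_mask(spec, 0)
kps = bs.extract_case_keypoints(mask, target_n=16)

points_map = bs.points_to_map(kps, mask.shape, radius=2)
full_map = bs.mask_to_map(mask)

print(f"mask foreground: {int(mask.sum())} px")
print(f"sampled-points map: {int(points_map.sum())} positive px "
      f"({len(kps)} disks of radius 2, kind={points_map.source_kind})")
print(f"boundary-mask map:  {int(full_map.sum())} positive px "
      f"(kind={full_map.source_kind})")
# The sparse map concentrates supervision on the key points; the dense map
# supervises the whole contour. Both are interchangeable in the map loss.
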