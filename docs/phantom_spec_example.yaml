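# Phantom description schema for `rvspect phantom make --spec ...`
#
# matrix_shape: integer triple, volume dimensions (x, y, z)
# voxel_size:   mm triple
# background:   activity (MBq/mL), density (g/cm^3), region label
# bodies:       painted in order; later bodies overwrite earlier ones.
#   shape:      sphere | ellipsoid | cylinder | box
#   center:     mm, relative to the matrix center
#   dimensions: full extents in mm —
#               sphere: [diameter]; ellipsoid: [dx, dy, dz];
#               cylinder (axis z): [diameter, height]; box: [ax, ay, az]
#   activity:   MBq/mL;  density: g/cm^3;  label: positive integer (unique)
#
# Voxel membership uses the voxel-center test; label 0 is reserved for
# "unlabelled".

matrix_shape: [64, 64, 64]
voxel_size: [4.42, 4.42, 4.42]
background:
  activity: 0.0
  density: 0.0
  label: 0
bodies:
  - shape: cylinder
    center: [0.0, 0.0, 0.0]
    dimensions: [220.0, 200.0]
    activity: 0.05
    density: 1.0
    label: 1
  - shape: sphere
    center: [-50.0, 0.0, 0.0]
    dimensions: [38.0]
    activity: 0.8
    density: 1.0
    label: 2
  - shape: ellipsoid
    center: [50.0, 20.0, 10.0]
    dimensions: [40.0, 55.0, 90.0]
    activity: 0.4
    density: 1.05
    label: 3
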