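"""oroflow — intraoral waterflow and skeletal kinematics analysis for
suction-feeding fish, from 3D X-ray particle-tracking trajectories.

The pipeline runs: trajectory I/O -> anatomical-frame transformation ->
feeding-phase segmentation -> path-curvature and displacement statistics ->
skeletal peak-sequence analysis, with tracer-fidelity physics (Stokes
density, reduced-order suction simulation) and a seeded synthetic-data
generator providing ground truth for every stage.
"""

from . import frames, kinematics, pathline, phases, physics, synthetic, trajectories
from .frames import (
    AnatomicalLandmarks,
    RigidPose,
    build_acs,
    fit_pose_series,
    fit_rigid_pose,
    to_anatomical,
    to_world,
)
from .kinematics import (
    KinematicTrace,
    gape_trace,
    hyoid_depression_trace,
    opercula_abduction_trace,
    peak_sequence,
)
from .pathline import (
    CurvatureProfile,
    TestResult,
    classify_flow_pattern,
    compare_curvature,
    intake_curvature_profiles,
    interval_max_curvature,
    menger_curvature,
    phase_distance,
    positional_correlation,
)
from .phases import (
    PhaseInterval,
    PhaseTable,
    SegmentationConfig,
    VelocitySeries,
    aggregate_water_velocity,
    compute_velocity,
    segment_phases,
    transition_periodicity,
)
from .physics import (
    FidelityReport,
    SuctionModel,
    cube_to_sphere_volume_ratio,
    default_release_points,
    fidelity_metrics,
    fidelity_of,
    settling_velocity,
    simulate_suction,
    stokes_density,
    terminal_velocity,
)
from .synthetic import (
    CARP,
    TILAPIA,
    SpeciesPreset,
    SyntheticWorld,
    generate_drop_test,
    generate_feeding_sequence,
    get_preset,
    write_fixture,
)
from .trajectories import (
    FluidProperties,
    TracerSpec,
    TrajectorySet,
    fill_gaps,
    read_trajectories,
    write_trajectories,
)

__version__ = "0.1.0"


def analyze_world(world, config: SegmentationConfig | None = None):
    """Run the standard pipeline on a synthetic world (or equivalent inputs).

    Fits neurocranium poses from the bone markers, builds the anatomical
    coordinate system from the landmarks, re-expresses all tracks in it,
    aggregates the water-tracer velocity and segments the phases.

    Returns ``(anatomical TrajectorySet, VelocitySeries, PhaseTable)``.
    """
    ts = world.trajectories
    marker_names = sorted(world.marker_reference)
    poses = fit_pose_series(ts, marker_names, world.marker_reference)
    acs = build_acs(poses, world.landmarks)
    anat = to_anatomical(ts, acs)
    vs = aggregate_water_velocity(anat, config)
    pt = segment_phases(vs, config)
    return anat, vs, pt
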