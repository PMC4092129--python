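"""Ultralight trajectory simulation, GPS/IMU streams, and Kalman AHRS fusion.

The aircraft flies a straight nominal track while the attitude wanders as
independent AR(1) processes (low-inertia platform instability).  Noisy GPS
positions and biased gyro rates are fused by a linear 12-state Kalman
filter (position, velocity, attitude, gyro bias) linearized about the
nominal track -- the small-angle regime.  Without an absolute attitude
reference yaw is unobservable (gyro-only heading drifts), so a low-rate
absolute attitude pseudo-measurement stream (gravity/horizon roll-pitch
plus magnetic yaw) is injected by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trajectory",
    "SensorStreams",
    "AhrsSolution",
    "simulate_trajectory",
    "simulate_sensors",
    "kalman_fuse",
    "dead_reckon_attitude",
    "gps_only_position",
]


@dataclass(frozen=True)
class Trajectory:
    """True per-line platform state.

    t: strictly increasing times at constant spacing t_int (s);
    pos: (n, 3) map-frame position (m), z = altitude;
    att: (n, 3) roll, pitch, yaw (rad); v: nominal ground speed (m/s).
    """

    t: np.ndarray
    pos: np.ndarray
    att: np.ndarray
    v: float
    t_int: float

    def __post_init__(self):
        if len(self.t) < 2:
            raise ValueError("trajectory needs at least two lines")
        dt = np.diff(self.t)
        if not np.allclose(dt, self.t_int, rtol=1e-9, atol=1e-12) or np.any(dt <= 0):
            raise ValueError("times must increase with constant spacing t_int")

    @property
    def n_lines(self) -> int:
        return len(self.t)

    @property
    def line_rate(self) -> float:
        return 1.0 / self.t_int

    def angular_rate(self) -> np.ndarray:
        """Body angular rate (rad/s) per line, small-angle Euler-rate approx."""
        return np.gradient(self.att, self.t, axis=0)


@dataclass(frozen=True)
class SensorStreams:
    """Raw measurement streams plus their (true) noise parameters."""

    imu_t: np.ndarray
    gyro: np.ndarray          # (m, 3) rad/s, biased + noisy
    gps_t: np.ndarray
    gps: np.ndarray           # (k, 3) m
    sigma_gps: float
    sigma_gyro: float
    sigma_b: float
    att_fix_t: np.ndarray | None = None
    att_fix: np.ndarray | None = None     # (j, 3) roll, pitch, yaw (rad)
    sigma_att_fix: float = 0.0

    @property
    def has_attitude_fix(self) -> bool:
        return self.att_fix_t is not None and len(self.att_fix_t) > 0


@dataclass(frozen=True)
class AhrsSolution:
    """Fused per-line pose estimate with covariance (12x12, PSD)."""

    t: np.ndarray
    pos: np.ndarray
    att: np.ndarray
    cov: np.ndarray           # (n, 12, 12)
    nis: np.ndarray = field(default=None, repr=False)  # GPS normalized innovation^2

    def __post_init__(self):
        if not (len(self.t) == len(self.pos) == len(self.att) == len(self.cov)):
            raise ValueError("per-line arrays must share length")


def simulate_trajectory(length_m: float, v: float, h: float, t_int: float,
                        perturbation: dict | None = None, seed: int = 0,
                        start: tuple[float, float] = (0.0, 0.0)) -> Trajectory:
    """Straight eastbound track at speed v and height h with AR(1) attitude.

    ``perturbation`` keys: sigma_roll/sigma_pitch/sigma_yaw (stationary std,
    rad) and rho (lag-1 correlation, |rho| < 1).  Number of lines is
    floor(length_m / (v * t_int)); with all sigmas 0 the flight is ideal.
    """
    if v <= 0 or h <= 0 or t_int <= 0:
        raise ValueError("v, h and t_int must be positive")
    p = dict(sigma_roll=0.0, sigma_pitch=0.0, sigma_yaw=0.0, rho=0.95)
    if perturbation:
        p.update(perturbation)
    sigmas = np.array([p["sigma_roll"], p["sigma_pitch"], p["sigma_yaw"]])
    rho = float(p["rho"])
    if np.any(sigmas < 0):
        raise ValueError("perturbation std must be >= 0")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")

    n = int(np.floor(length_m / (v * t_int)))
    if n < 2:
        raise ValueError("track too short for the given speed and line rate")
    t = np.arange(n) * t_int
    pos = np.column_stack([start[0] + v * t,
                           np.full(n, start[1]),
                           np.full(n, float(h))])

    rng = np.random.default_rng(seed)
    att = np.zeros((n, 3))
    if np.any(sigmas > 0):
        innov_scale = np.sqrt(1.0 - rho ** 2)
        eps = rng.standard_normal((n, 3))
        att[0] = sigmas * eps[0]
        for k in range(1, n):        # AR(1), stationary std = sigma
            att[k] = rho * att[k - 1] + sigmas * innov_scale * eps[k]
    return Trajectory(t=t, pos=pos, att=att, v=float(v), t_int=float(t_int))


def _interp_rows(tq: np.ndarray, t: np.ndarray, rows: np.ndarray) -> np.ndarray:
    return np.column_stack([np.interp(tq, t, rows[:, i]) for i in range(rows.shape[1])])


def simulate_sensors(traj: Trajectory, sigma_gps: float = 0.2,
                     sigma_gyro: float = 0.002, sigma_b: float = 1e-5,
                     gps_rate: float = 10.0, imu_rate: float | None = None,
                     attitude_fix: bool = True, att_fix_rate: float = 10.0,
                     sigma_att_fix: float = 3e-4,
                     seed: int = 0) -> SensorStreams:
    """Noisy GPS positions and biased gyro rates sampled from the truth.

    GPS = true position + white Gaussian noise; gyro = true angular rate +
    bias(t) + white noise, where the bias is a per-axis random walk with
    increment std sigma_b * sqrt(dt).  The gyro is an integrating-rate
    sensor: sample k reports the mean rate over [t_k, t_k+1], so
    noise-free integration reconstructs the attitude exactly at sample
    times.  The optional absolute-attitude stream measures roll/pitch/yaw
    at low rate (gravity/horizon reference plus a magnetic heading;
    without it yaw stays unobservable).  IMU rate defaults to the line
    rate and may not be lower.
    """
    if min(sigma_gps, sigma_gyro, sigma_b, sigma_att_fix) < 0:
        raise ValueError("noise sigmas must be >= 0")
    if imu_rate is None:
        imu_rate = traj.line_rate
    if imu_rate < traj.line_rate - 1e-9:
        raise ValueError("IMU rate must be >= line rate")
    rng = np.random.default_rng(seed)
    t0, t1 = traj.t[0], traj.t[-1]

    imu_t = np.arange(t0, t1 + 1e-12, 1.0 / imu_rate)
    dt = 1.0 / imu_rate
    att_imu = _interp_rows(imu_t, traj.t, traj.att)
    true_rate = np.empty_like(att_imu)       # forward increment over [t_k, t_k+1]
    true_rate[:-1] = np.diff(att_imu, axis=0) / dt
    true_rate[-1] = true_rate[-2]
    bias = np.cumsum(rng.standard_normal((len(imu_t), 3)) * sigma_b * np.sqrt(dt), axis=0)
    gyro = true_rate + bias + rng.standard_normal((len(imu_t), 3)) * sigma_gyro

    # GPS likewise timestamped on the IMU clock (receiver/IMU time sync);
    # at ~18 m/s a fraction of a line period of skew is tens of cm
    stride_gps = max(int(round(imu_rate / gps_rate)), 1)
    gps_t = imu_t[::stride_gps]
    gps = _interp_rows(gps_t, traj.t, traj.pos) + rng.standard_normal((len(gps_t), 3)) * sigma_gps

    att_fix_t = att_fix = None
    if attitude_fix:
        # timestamped on the IMU clock: attitude moves several mrad per
        # line, so fixes must refer to exact sample instants
        stride = max(int(round(imu_rate / att_fix_rate)), 1)
        att_fix_t = imu_t[::stride]
        true_att = _interp_rows(att_fix_t, traj.t, traj.att)
        att_fix = true_att + rng.standard_normal((len(att_fix_t), 3)) * sigma_att_fix

    return SensorStreams(imu_t=imu_t, gyro=gyro, gps_t=gps_t, gps=gps,
                         sigma_gps=sigma_gps, sigma_gyro=sigma_gyro, sigma_b=sigma_b,
                         att_fix_t=att_fix_t, att_fix=att_fix,
                         sigma_att_fix=sigma_att_fix)


# state layout: [p(0:3), v(3:6), att(6:9), bias(9:12)]
_IP, _IV, _IA, _IB = slice(0, 3), slice(3, 6), slice(6, 9), slice(9, 12)


def kalman_fuse(streams: SensorStreams, line_t: np.ndarray | None = None,
                init_state: np.ndarray | None = None,
                init_cov: np.ndarray | None = None,
                q_vel: float = 0.05, q_pos: float = 1e-6) -> AhrsSolution:
    """Fuse GPS + gyro (+ optional roll/pitch fixes) into a per-line AHRS.

    Linear Kalman filter stepped at the IMU rate: the prediction integrates
    the bias-corrected gyro into attitude and propagates constant-velocity
    position; GPS position and absolute attitude updates are applied at
    their own timestamps.  Estimates are linearly interpolated onto
    ``line_t`` (defaults to the IMU timestamps).  The GPS normalized
    innovation squared sequence is kept for consistency diagnostics.
    """
    if len(streams.imu_t) < 2:
        raise ValueError("empty or degenerate IMU stream")
    imu_t, gyro = streams.imu_t, streams.gyro
    n = len(imu_t)

    x = np.zeros(12)
    if init_state is not None:
        x = np.asarray(init_state, dtype=float).copy()
    else:
        x[_IP] = streams.gps[0]
        if len(streams.gps_t) > 1:
            x[_IV] = (streams.gps[1] - streams.gps[0]) / (streams.gps_t[1] - streams.gps_t[0])
    if init_cov is not None:
        P = np.asarray(init_cov, dtype=float).copy()
    else:
        P = np.diag(np.r_[np.full(3, max(streams.sigma_gps, 1e-3) ** 2),
                          np.full(3, max(8.0 * streams.sigma_gps, 1e-2) ** 2),
                          np.full(3, (2 * np.pi / 180) ** 2),
                          np.full(3, 1e-4)])
    if np.any(np.linalg.eigvalsh(P) < -1e-12):
        raise np.linalg.LinAlgError("initial covariance not positive semi-definite")

    r_gps = max(streams.sigma_gps, 1e-4) ** 2
    r_att = max(streams.sigma_att_fix, 1e-5) ** 2
    sg = max(streams.sigma_gyro, 1e-7)
    sb = max(streams.sigma_b, 1e-9)

    H_gps = np.zeros((3, 12)); H_gps[:, _IP] = np.eye(3)
    H_att = np.zeros((3, 12)); H_att[:, _IA] = np.eye(3)

    gps_idx = np.searchsorted(imu_t, streams.gps_t - 1e-9)
    gps_by_step = {}
    for j, k in enumerate(gps_idx):
        gps_by_step.setdefault(min(int(k), n - 1), []).append(j)
    att_by_step = {}
    if streams.has_attitude_fix:
        att_idx = np.searchsorted(imu_t, streams.att_fix_t - 1e-9)
        for j, k in enumerate(att_idx):
            att_by_step.setdefault(min(int(k), n - 1), []).append(j)

    xs = np.empty((n, 12))
    Ps = np.empty((n, 12, 12))
    nis = []

    def update(z, H, r):
        nonlocal x, P
        y = z - H @ x
        S = H @ P @ H.T + r * np.eye(len(z))
        try:
            K = np.linalg.solve(S, H @ P).T
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(f"singular innovation covariance: {e}") from e
        x = x + K @ y
        IKH = np.eye(12) - K @ H
        P = IKH @ P @ IKH.T + r * (K @ K.T)    # Joseph form
        return float(y @ np.linalg.solve(S, y))

    for k in range(n):
        if k > 0:
            dt = imu_t[k] - imu_t[k - 1]
            F = np.eye(12)
            F[0, 3] = F[1, 4] = F[2, 5] = dt
            F[6, 9] = F[7, 10] = F[8, 11] = -dt
            x = F @ x
            x[_IA] += gyro[k - 1] * dt      # control input: raw gyro increment
            Q = np.zeros((12, 12))
            Q[_IP, _IP] = np.eye(3) * q_pos * dt
            Q[_IV, _IV] = np.eye(3) * q_vel * dt
            Q[_IA, _IA] = np.eye(3) * (sg ** 2) * dt
            Q[_IB, _IB] = np.eye(3) * (sb ** 2) * dt
            P = F @ P @ F.T + Q
        for j in gps_by_step.get(k, []):
            nis.append(update(streams.gps[j], H_gps, r_gps))
        for j in att_by_step.get(k, []):
            update(streams.att_fix[j], H_att, r_att)
        xs[k] = x
        Ps[k] = P

    if line_t is None:
        line_t = imu_t
        pos, att = xs[:, _IP], xs[:, _IA]
        cov = Ps
    else:
        pos = _interp_rows(line_t, imu_t, xs[:, _IP])
        att = _interp_rows(line_t, imu_t, xs[:, _IA])
        nearest = np.clip(np.searchsorted(imu_t, line_t), 0, n - 1)
        cov = Ps[nearest]
    return AhrsSolution(t=np.asarray(line_t, float), pos=pos, att=att, cov=cov,
                        nis=np.asarray(nis))


def dead_reckon_attitude(streams: SensorStreams, att0: np.ndarray,
                         line_t: np.ndarray | None = None) -> np.ndarray:
    """Gyro-only attitude: integrate raw rates from a known initial attitude.

    No bias estimation -- the baseline the fused solution must beat.
    """
    dt = np.diff(streams.imu_t)
    att = np.vstack([att0, att0 + np.cumsum(streams.gyro[:-1] * dt[:, None], axis=0)])
    if line_t is None:
        return att
    return _interp_rows(line_t, streams.imu_t, att)


def gps_only_position(streams: SensorStreams, line_t: np.ndarray) -> np.ndarray:
    """Raw GPS linearly interpolated to line times (no filtering baseline)."""
    return _interp_rows(line_t, streams.gps_t, streams.gps)
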