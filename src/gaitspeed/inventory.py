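"""Device, sensor and feature-name bookkeeping for the wearable set.

The wearable set comprises a smartphone carried in the trouser pocket, a
wrist-worn smartwatch and a pair of instrumented ("smart") shoes.  Every
sensor group is tri-axial and sampled at 50 Hz:

=========== ========================= =========
device      sensor groups             channels
=========== ========================= =========
phone       accelerometer, orientation  x,y,z / azimuth,pitch,roll
watch       accelerometer, gyroscope    x,y,z
shoe (x2)   accelerometer, gyroscope,   x,y,z / p1,p2,p3
            pressure
=========== ========================= =========

Feature names follow the scheme ``STATISTIC_SENSOR_FILTERMODE_COMPONENT_DEVICE``
(``SMA`` omits the component, being computed once per sensor), e.g.
``RMS_acc_lp_mod_dev_2`` is the root-mean-square of the modulus of the
low-pass-filtered watch accelerometer.  Non-Cartesian channels (orientation
angles, the three insole pressure cells) are labelled positionally as
x / y / z.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

SAMPLING_RATE_HZ: float = 50.0

#: physical devices, in deterministic output order
DEVICES: tuple[str, ...] = ("phone", "watch", "shoe_left", "shoe_right")

#: device codes used in feature names
DEVICE_CODES: Mapping[str, str] = {
    "phone": "dev_1",
    "watch": "dev_2",
    "shoe_left": "dev_3",
    "shoe_right": "dev_4",
}
CODE_TO_DEVICE: Mapping[str, str] = {v: k for k, v in DEVICE_CODES.items()}

#: sensor groups and channel names per physical device
SENSOR_GROUPS: Mapping[str, Mapping[str, tuple[str, str, str]]] = {
    "phone": {
        "acc": ("x", "y", "z"),
        "ori": ("azimuth", "pitch", "roll"),
    },
    "watch": {
        "acc": ("x", "y", "z"),
        "gyr": ("x", "y", "z"),
    },
    "shoe_left": {
        "acc": ("x", "y", "z"),
        "gyr": ("x", "y", "z"),
        "press": ("p1", "p2", "p3"),
    },
    "shoe_right": {
        "acc": ("x", "y", "z"),
        "gyr": ("x", "y", "z"),
        "press": ("p1", "p2", "p3"),
    },
}

#: accelerometer axis aligned with gravity for each device (phone carried
#: screen-to-thigh with its y axis up; watch and shoes approximately z-up)
VERTICAL_AXIS: Mapping[str, str] = {
    "phone": "y",
    "watch": "z",
    "shoe_left": "z",
    "shoe_right": "z",
}

#: the windowed statistics, in canonical order
STATISTICS: tuple[str, ...] = (
    "MEAN", "STD", "CV", "RMS", "RNG", "MAX", "MCR", "PF", "ENT",
)
#: SMA is computed once per sensor (on the three channels jointly)
SMA: str = "SMA"

FILTER_MODES: tuple[str, str] = ("lp", "lp-hp")
COMPONENTS: tuple[str, ...] = ("x", "y", "z", "mod")

#: the seven device combinations, expressed over logical devices
#: (``shoes`` = the instrumented pair)
COMBINATIONS: Mapping[str, tuple[str, ...]] = {
    "phone": ("phone",),
    "watch": ("watch",),
    "shoes": ("shoes",),
    "phone+watch": ("phone", "watch"),
    "phone+shoes": ("phone", "shoes"),
    "watch+shoes": ("watch", "shoes"),
    "all": ("phone", "watch", "shoes"),
}

#: combinations each logical device takes part in (4 of the 7 each)
DEVICE_COMBINATIONS: Mapping[str, tuple[str, ...]] = {
    dev: tuple(name for name, members in COMBINATIONS.items() if dev in members)
    for dev in ("phone", "watch", "shoes")
}

FEATURES_PER_SENSOR: int = 2 * (len(STATISTICS) * len(COMPONENTS) + 1)  # 74


def physical_devices(logical: Iterable[str], both_shoes: bool = True) -> tuple[str, ...]:
    """Expand logical device names ({phone, watch, shoes}) to physical ones."""
    out: list[str] = []
    for dev in logical:
        if dev == "shoes":
            out.append("shoe_left")
            if both_shoes:
                out.append("shoe_right")
        elif dev in ("phone", "watch"):
            out.append(dev)
        else:
            raise ValueError(f"unknown logical device {dev!r}")
    return tuple(out)


def combination_devices(combination: str, both_shoes: bool = True) -> tuple[str, ...]:
    """Physical devices contributing to a named combination."""
    try:
        logical = COMBINATIONS[combination]
    except KeyError:
        raise ValueError(
            f"unknown combination {combination!r}; expected one of {list(COMBINATIONS)}"
        ) from None
    return physical_devices(logical, both_shoes=both_shoes)


def sensor_feature_names(sensor: str, device_code: str) -> list[str]:
    """The 74 feature names for one tri-axial sensor group on one device.

    Per filter mode: 9 statistics x 4 components (x, y, z, modulus) plus a
    single SMA; two filter modes give 74 names.
    """
    names: list[str] = []
    for mode in FILTER_MODES:
        for stat in STATISTICS:
            for comp in COMPONENTS:
                names.append(f"{stat}_{sensor}_{mode}_{comp}_{device_code}")
        names.append(f"{SMA}_{sensor}_{mode}_{device_code}")
    return names


def device_feature_names(device: str) -> list[str]:
    """All feature names for one physical device, in deterministic order."""
    code = DEVICE_CODES[device]
    names: list[str] = []
    for sensor in SENSOR_GROUPS[device]:
        names.extend(sensor_feature_names(sensor, code))
    return names


def pool_feature_names(combination: str, both_shoes: bool = True) -> list[str]:
    """Candidate feature pool (ordered names) for a device combination."""
    names: list[str] = []
    for dev in combination_devices(combination, both_shoes=both_shoes):
        names.extend(device_feature_names(dev))
    return names


def count_features(logical: Iterable[str]) -> int:
    """Combinatorial feature count for a set of logical devices.

    The count follows the per-device sensor inventory with 74 features per
    sensor group: phone and watch carry two groups (148 each); the shoes'
    inventory (accelerometer + gyroscope + pressure) counts three groups
    (222); all devices together give 518.
    """
    groups = {"phone": 2, "watch": 2, "shoes": 3}
    total = 0
    for dev in set(logical):
        if dev not in groups:
            raise ValueError(f"unknown logical device {dev!r}")
        total += groups[dev] * FEATURES_PER_SENSOR
    return total


def parse_feature_name(name: str) -> dict[str, str]:
    """Split a feature name into its statistic/sensor/mode/component/device."""
    parts = name.split("_")
    if len(parts) == 5 and parts[0] == SMA and parts[3] == "dev":
        stat, sensor, mode, comp = parts[0], parts[1], parts[2], ""
        code = f"{parts[3]}_{parts[4]}"
    elif len(parts) == 6 and parts[4] == "dev":
        stat, sensor, mode, comp = parts[0], parts[1], parts[2], parts[3]
        code = f"{parts[4]}_{parts[5]}"
    else:
        raise ValueError(f"malformed feature name {name!r}")
    return {
        "statistic": stat,
        "sensor": sensor,
        "filter_mode": mode,
        "component": comp,
        "device_code": code,
    }


def device_of_feature(name: str) -> str:
    """Logical device ({phone, watch, shoes}) a feature belongs to."""
    code = parse_feature_name(name)["device_code"]
    physical = CODE_TO_DEVICE[code]
    return "shoes" if physical.startswith("shoe") else physical
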