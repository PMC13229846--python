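{
  "description": "Nominal sRGB values (0-255) for the 24 patches of the classic colour checker card, row-major from the top-left patch. Widely published nominal values for the pre-2014 reference card; override per card batch if the vendor supplies measured values.",
  "chips": [
    {"chip_id": 1,  "name": "dark skin",      "srgb": [115, 82, 68]},
    {"chip_id": 2,  "name": "light skin",     "srgb": [194, 150, 130]},
    {"chip_id": 3,  "name": "blue sky",       "srgb": [98, 122, 157]},
    {"chip_id": 4,  "name": "foliage",        "srgb": [87, 108, 67]},
    {"chip_id": 5,  "name": "blue flower",    "srgb": [133, 128, 177]},
    {"chip_id": 6,  "name": "bluish green",   "srgb": [103, 189, 170]},
    {"chip_id": 7,  "name": "orange",         "srgb": [214, 126, 44]},
    {"chip_id": 8,  "name": "purplish blue",  "srgb": [80, 91, 166]},
    {"chip_id": 9,  "name": "moderate red",   "srgb": [193, 90, 99]},
    {"chip_id": 10, "name": "purple",         "srgb": [94, 60, 108]},
    {"chip_id": 11, "name": "yellow green",   "srgb": [157, 188, 64]},
    {"chip_id": 12, "name": "orange yellow",  "srgb": [224, 163, 46]},
    {"chip_id": 13, "name": "blue",           "srgb": [56, 61, 150]},
    {"chip_id": 14, "name": "green",          "srgb": [70, 148, 73]},
    {"chip_id": 15, "name": "red",            "srgb": [175, 54, 60]},
    {"chip_id": 16, "name": "yellow",         "srgb": [231, 199, 31]},
    {"chip_id": 17, "name": "magenta",        "srgb": [187, 86, 149]},
    {"chip_id": 18, "name": "cyan",           "srgb": [8, 133, 161]},
    {"chip_id": 19, "name": "white 9.5",      "srgb": [243, 243, 242]},
    {"chip_id": 20, "name": "neutral 8",      "srgb": [200, 200, 200]},
    {"chip_id": 21, "name": "neutral 6.5",    "srgb": [160, 160, 160]},
    {"chip_id": 22, "name": "neutral 5",      "srgb": [122, 121, 120]},
    {"chip_id": 23, "name": "neutral 3.5",    "srgb": [85, 85, 85]},
    {"chip_id": 24, "name": "black 2",        "srgb": [52, 52, 52]}
  ]
}
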