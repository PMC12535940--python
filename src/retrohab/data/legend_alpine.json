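{
  "l1": [
    {"code": 1, "name": "Rocks"},
    {"code": 2, "name": "Snow and glaciers"},
    {"code": 3, "name": "Water"},
    {"code": 4, "name": "Broadleaved"},
    {"code": 5, "name": "Coniferous"},
    {"code": 6, "name": "Grassland"},
    {"code": 7, "name": "Shrubland"},
    {"code": 8, "name": "Wetland"}
  ],
  "l2": [
    {"code": 41, "name": "Scrubland and woods of maple, linden and ash trees", "parent": 4, "natura2000": []},
    {"code": 42, "name": "Oak forest", "parent": 4, "natura2000": []},
    {"code": 43, "name": "Mixed broadleaved forests", "parent": 4, "natura2000": []},
    {"code": 44, "name": "Mixed hygrophilous woods of broadleaved trees", "parent": 4, "natura2000": ["91E0"]},
    {"code": 45, "name": "Chestnut groves", "parent": 4, "natura2000": ["9260"]},
    {"code": 46, "name": "Beech forests", "parent": 4, "natura2000": ["9110", "9130", "9150"]},
    {"code": 51, "name": "Fir forests", "parent": 5, "natura2000": []},
    {"code": 52, "name": "Larix decidua and/or Pinus cembra forests", "parent": 5, "natura2000": ["9420"]},
    {"code": 53, "name": "Mountain pine forests (Pinus uncinata)", "parent": 5, "natura2000": ["9430"]},
    {"code": 54, "name": "Mixed coniferous forests", "parent": 5, "natura2000": []},
    {"code": 55, "name": "Sparse coniferous forests", "parent": 5, "natura2000": []},
    {"code": 56, "name": "Spruce forests", "parent": 5, "natura2000": ["9410"]},
    {"code": 57, "name": "Scots pine forests", "parent": 5, "natura2000": []},
    {"code": 61, "name": "Subalpine and alpine acidophilic grasslands", "parent": 6, "natura2000": ["6150", "6230*"]},
    {"code": 62, "name": "Subalpine and alpine calcicolous grasslands", "parent": 6, "natura2000": ["6170"]},
    {"code": 63, "name": "Hydrophilous tall herb communities of the alpine plain", "parent": 6, "natura2000": ["6430"]},
    {"code": 64, "name": "Arid and thermophilic grasslands", "parent": 6, "natura2000": ["6210", "6240*"]},
    {"code": 65, "name": "Montane grasslands", "parent": 6, "natura2000": ["6520"]},
    {"code": 71, "name": "Woody riparian vegetation of watercourses", "parent": 7, "natura2000": ["3230", "3240"]},
    {"code": 72, "name": "Green alder shrubs", "parent": 7, "natura2000": []},
    {"code": 73, "name": "Shrubland (without distinction of species)", "parent": 7, "natura2000": []},
    {"code": 74, "name": "Sub-arctic shrublands with Salix sp.", "parent": 7, "natura2000": ["4080"]},
    {"code": 75, "name": "Subalpine and alpine heaths", "parent": 7, "natura2000": ["4060"]}
  ]
}
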