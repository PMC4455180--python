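{
 "crs_note": "synthetic - coordinates are approximate city lon/lat, not from the source data",
 "rows": [
  {"row": 1, "name": "Tijuana", "state": "Baja California Norte", "x": -117.04, "y": 32.52, "populations": [3122400], "economic_powers": [8]},
  {"row": 2, "name": "Nogales", "state": "Sonora", "x": -110.95, "y": 31.32, "populations": [2499263], "economic_powers": [12]},
  {"row": 3, "name": "Ciudad Juarez", "state": "Chihuahua", "x": -106.48, "y": 31.74, "populations": [3376052], "economic_powers": [5]},
  {"row": 4, "name": "Hermosillo", "state": "Sonora", "x": -110.97, "y": 29.07, "populations": [2499263], "economic_powers": [12]},
  {"row": 5, "name": "Chihuahua", "state": "Chihuahua", "x": -106.09, "y": 28.63, "populations": [3376052], "economic_powers": [5]},
  {"row": 6, "name": "Nuevo Laredo", "state": "Tamaulipas", "x": -99.55, "y": 27.48, "populations": [3174134], "economic_powers": [11]},
  {"row": 7, "name": "Monterrey", "state": "Nuevo Leon", "x": -100.32, "y": 25.67, "populations": [4420909], "economic_powers": [3]},
  {"row": 8, "name": "Mazatlan", "state": "Sinaloa", "x": -106.42, "y": 23.25, "populations": [2650499], "economic_powers": [15]},
  {"row": 9, "name": "Ciudad Victoria", "state": "Tamaulipas", "x": -99.15, "y": 23.73, "populations": [3174134], "economic_powers": [11]},
  {"row": 10, "name": "San Luis Potosi", "state": "San Luis Potosi", "x": -100.98, "y": 22.15, "populations": [2479450], "economic_powers": [14]},
  {"row": 11, "name": "Guadalajara", "state": "Jalisco", "x": -103.35, "y": 20.67, "populations": [6989304], "economic_powers": [4]},
  {"row": 12, "name": "Leon and Guanajuato", "state": "Guanajuato", "x": -101.68, "y": 21.12, "populations": [5033276], "economic_powers": [9]},
  {"row": 13, "name": "Morelia", "state": "Michoacan", "x": -101.19, "y": 19.7, "populations": [3971225], "economic_powers": [22]},
  {"row": 14, "name": "Edo. Mexico, DF, Puebla", "state": "*", "x": -99.13, "y": 19.43, "populations": [14739060, 8839361, 5624104], "economic_powers": [2, 1, 7]},
  {"row": 15, "name": "Xalapa, Veracruz", "state": "Veracruz", "x": -96.92, "y": 19.54, "populations": [7270413], "economic_powers": [6]},
  {"row": 16, "name": "Chilpancingo, Acapulco", "state": "Guerrero", "x": -99.5, "y": 17.55, "populations": [3143292], "economic_powers": [18]},
  {"row": 17, "name": "Oaxaca, Huatulco", "state": "Oaxaca", "x": -96.72, "y": 17.07, "populations": [3551710], "economic_powers": [20]},
  {"row": 18, "name": "Tuxtla Gutierrez", "state": "Chiapas", "x": -93.12, "y": 16.75, "populations": [4483866], "economic_powers": [17]},
  {"row": 19, "name": "Merida and Cancun", "state": "Yucatan, Quintana Roo", "x": -89.62, "y": 20.97, "populations": [1909965, 1290300], "economic_powers": [21, 19]}
 ]
}
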