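{
  "cycle_id": "demo-cycle",
  "entries": {
    "1": {
      "breakfast": {
        "regular1800": [
          {"item_id": "oatmeal", "servings": 1},
          {"item_id": "scrambled_eggs", "servings": 1},
          {"item_id": "toast_wheat", "servings": 2},
          {"item_id": "orange_juice", "servings": 1},
          {"item_id": "coffee", "servings": 1}
        ],
        "full_liquid": [
          {"item_id": "broth_chicken", "servings": 1},
          {"item_id": "apple_juice", "servings": 1},
          {"item_id": "gelatin", "servings": 1},
          {"item_id": "tea", "servings": 1}
        ]
      },
      "lunch": {
        "regular1800": [
          {"item_id": "beef_stew", "servings": 1},
          {"item_id": "rice_white", "servings": 1},
          {"item_id": "dinner_roll", "servings": 1},
          {"item_id": "fruit_cup", "servings": 1},
          {"item_id": "milk_2pct", "servings": 1}
        ],
        "full_liquid": [
          {"item_id": "broth_chicken", "servings": 1},
          {"item_id": "ice_cream_van", "servings": 1},
          {"item_id": "apple_juice", "servings": 1}
        ]
      },
      "dinner": {
        "regular1800": [
          {"item_id": "chicken_breast", "servings": 1},
          {"item_id": "mashed_potato", "servings": 1},
          {"item_id": "green_beans", "servings": 1},
          {"item_id": "dinner_roll", "servings": 1},
          {"item_id": "pudding_van", "servings": 1},
          {"item_id": "tea", "servings": 1}
        ],
        "full_liquid": [
          {"item_id": "broth_chicken", "servings": 1},
          {"item_id": "gelatin", "servings": 1},
          {"item_id": "ice_cream_van", "servings": 1}
        ]
      }
    }
  }
}
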